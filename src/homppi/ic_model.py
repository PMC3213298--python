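"""Linear interface-conservation (IC) models.

The IC score of a query-template pair -- the Matthews correlation between
transferred template interface labels and the query's true labels -- is
approximated by a linear function of alignment statistics.  Two models are
shipped with published default coefficients:

* NPS:  IC = b0 + b1*log(EVal) + b2*PositiveScore + b3*log(LAL)
* PS:   IC = b0 + b1*avg log(EVal) + b2*avg PositiveScore
             + b3*Frac_AA' + b4*Frac_BB'

with positive scores in percent (0-100) and fractions in [0,1].  The model
is used only to *rank* candidate templates, so predictions are not clipped
to [-1, 1].
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from homppi.blast_io import AlignmentStats
from homppi.zoning import PSStats

__all__ = [
    "NPS_DEFAULT_COEF",
    "PS_DEFAULT_COEF",
    "NPS_FEATURES",
    "PS_FEATURES",
    "InterfaceConservationRegressor",
    "FittingError",
    "predict_ic",
    "fit_ic_model",
    "rank_templates",
    "stats_vector",
]


class FittingError(ValueError):
    """Raised when the IC regression cannot be fit (too few rows, collinearity)."""


#: Default NPS coefficients over [1, log_eval, positive_score, log_lal].
NPS_DEFAULT_COEF = (-0.5655, -0.0004, 0.0037, 0.1057)
#: Default PS coefficients over [1, avg_log_eval, avg_positive, frac_aa, frac_bb].
PS_DEFAULT_COEF = (-0.505, 0.001, 0.009, 0.341, 0.205)

NPS_FEATURES = ("log_eval", "positive_score", "log_lal")
PS_FEATURES = ("avg_log_eval", "avg_positive", "frac_aa", "frac_bb")


def stats_vector(stats: Union[AlignmentStats, PSStats]) -> np.ndarray:
    """Feature row for one alignment (NPS) or one homo-interolog (PS)."""
    if isinstance(stats, AlignmentStats):
        return np.array([stats.log_eval, stats.positive_score, stats.log_lal])
    if isinstance(stats, PSStats):
        return np.array([stats.avg_log_eval, stats.avg_positive,
                         stats.frac_aa, stats.frac_bb])
    raise TypeError(f"unsupported stats type: {type(stats).__name__}")


class InterfaceConservationRegressor(BaseEstimator, RegressorMixin):
    """Linear IC model as a scikit-learn estimator.

    Parameters
    ----------
    kind : {"nps", "ps"}
        Selects the feature set: 3 alignment statistics for NPS, 4
        homo-interolog statistics for PS.
    coefficients : sequence of float, optional
        Intercept-first coefficient vector.  When omitted the published
        defaults for ``kind`` are used and ``provenance_`` is
        ``"paper_default"``; :meth:`fit` replaces them (``"refit"``).

    Attributes
    ----------
    coef_ : ndarray
        Intercept-first coefficients actually used by :meth:`predict`.
    bse_ : ndarray
        OLS standard errors (after :meth:`fit`).
    tvalues_ : ndarray
        OLS t-statistics (after :meth:`fit`).
    """

    def __init__(self, kind: str = "nps",
                 coefficients: Optional[Sequence[float]] = None):
        self.kind = kind
        self.coefficients = coefficients

    @property
    def feature_names(self) -> tuple[str, ...]:
        return NPS_FEATURES if self.kind == "nps" else PS_FEATURES

    def _default_coef(self) -> np.ndarray:
        if self.kind == "nps":
            return np.array(NPS_DEFAULT_COEF)
        if self.kind == "ps":
            return np.array(PS_DEFAULT_COEF)
        raise ValueError(f"kind must be 'nps' or 'ps', got {self.kind!r}")

    def _ensure_coef(self) -> None:
        if hasattr(self, "coef_"):
            return
        if self.coefficients is not None:
            coef = np.asarray(self.coefficients, dtype=float)
            if coef.shape != self._default_coef().shape:
                raise ValueError(
                    f"{self.kind} model needs {self._default_coef().size} "
                    f"coefficients, got {coef.size}")
            self.coef_ = coef
        else:
            self.coef_ = self._default_coef()
        self.provenance_ = "paper_default" if self.coefficients is None else "custom"

    def fit(self, X, y) -> "InterfaceConservationRegressor":
        """Ordinary least squares refit on (statistics, observed IC) rows.

        ``X`` has one column per feature (no intercept column); the
        intercept is added internally.  Requires at least p + 2 rows and a
        full-rank design.
        """
        p = len(self.feature_names) + 1
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != p - 1:
            raise ValueError(f"X must have {p - 1} columns for kind={self.kind!r}")
        if X.shape[0] < p + 1:
            raise FittingError(
                f"need at least {p + 1} observations to fit {p} coefficients, "
                f"got {X.shape[0]}")
        design = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(design) < p:
            raise FittingError(
                "rank-deficient design; collinear columns among: "
                + ", ".join(_collinear_columns(design, self.feature_names)))
        res = sm.OLS(y, design).fit()
        self.coef_ = np.asarray(res.params)
        self.bse_ = np.asarray(res.bse)
        self.tvalues_ = np.asarray(res.tvalues)
        self.provenance_ = "refit"
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted IC = b0 + sum_i b_i x_i for each row (unclipped)."""
        self._ensure_coef()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite value in IC model input")
        if X.shape[1] != self.coef_.size - 1:
            raise ValueError(f"expected {self.coef_.size - 1} features, got {X.shape[1]}")
        return self.coef_[0] + X @ self.coef_[1:]

    def predict_one(self, stats: Union[AlignmentStats, PSStats]) -> float:
        return float(self.predict(stats_vector(stats)[None, :])[0])


def _collinear_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the feature columns involved in the rank deficiency."""
    labels = ["intercept", *names]
    bad = []
    full_rank = np.linalg.matrix_rank(design)
    for j in range(design.shape[1]):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(labels[j])
    return bad or labels


def predict_ic(model: InterfaceConservationRegressor,
               stats: Union[AlignmentStats, PSStats]) -> float:
    """Predicted interface conservation for one pair (thin wrapper)."""
    kind = "nps" if isinstance(stats, AlignmentStats) else "ps"
    if kind != model.kind:
        raise TypeError(f"{type(stats).__name__} passed to a {model.kind} model")
    return model.predict_one(stats)


def fit_ic_model(observations: Sequence[tuple[Union[AlignmentStats, PSStats], float]],
                 kind: str) -> InterfaceConservationRegressor:
    """OLS fit of an IC model from (stats, observed IC) pairs."""
    X = np.array([stats_vector(s) for s, _ in observations])
    y = np.array([ic for _, ic in observations])
    return InterfaceConservationRegressor(kind=kind).fit(X, y)


def rank_templates(hits, model: InterfaceConservationRegressor, k: int = 10):
    """Top-k hits by predicted IC, descending.

    ``hits`` is a sequence of ``(template, stats)`` pairs already filtered
    to one homology zone.  Ties are broken deterministically by (lower
    EVal if the template carries an alignment record, then template id).
    """
    def sort_key(item):
        template, stats = item
        ic = model.predict_one(stats)
        ev = getattr(template, "eval", None)
        if ev is None:
            ev = getattr(getattr(template, "record", None), "eval", float("inf"))
        tid = getattr(template, "template_id", None) or str(template)
        return (-ic, ev, tid)

    return sorted(hits, key=sort_key)[:k]
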