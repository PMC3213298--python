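import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from homppi.blast_io import AlignmentRecord
from homppi.structure_interface import LabelTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20110617)


def make_record(q_aln: str, t_aln: str, eval: float = 1e-60,
                query_id: str = "q", template_id: str = "t",
                query_len: int | None = None, template_len: int | None = None,
                q_start: int = 1, t_start: int = 1,
                n_identical: int | None = None,
                n_positive: int | None = None) -> AlignmentRecord:
    """Build a consistent alignment record from aligned strings."""
    q_res = sum(1 for c in q_aln if c != "-")
    t_res = sum(1 for c in t_aln if c != "-")
    if n_identical is None:
        n_identical = sum(1 for a, b in zip(q_aln, t_aln) if a == b and a != "-")
    if n_positive is None:
        n_positive = n_identical
    rec = AlignmentRecord(
        query_id=query_id, template_id=template_id, eval=eval,
        n_identical=n_identical, n_positive=n_positive, lal=len(q_aln),
        query_len=query_len if query_len is not None else q_start - 1 + q_res,
        template_len=template_len if template_len is not None else t_start - 1 + t_res,
        q_aln=q_aln, t_aln=t_aln,
        q_start=q_start, q_end=q_start + q_res - 1,
        t_start=t_start, t_end=t_start + t_res - 1,
    )
    rec.validate()
    return rec


def track(labels: str) -> LabelTrack:
    return LabelTrack(labels)
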