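"""Safe / Twilight / Dark homology zones.

Query-template pairs (NPS) and homo-interolog pairs (PS) are binned into
zones of expected interface conservation by thresholds on BLAST alignment
statistics.  Classification is strictest-first: a pair lands in the best
zone whose every condition holds.  Because the zone tables cap log(EVal) at
1 while the BLAST search itself admits EVal <= 10 (ln 10 ~ 2.303), a hit
with 1 < log(EVal) <= ln 10 belongs to no zone at all.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import yaml

from homppi.blast_io import AlignmentStats

__all__ = [
    "Zone",
    "ZoneThresholds",
    "PSStats",
    "NPS_ZONES",
    "PS_ZONES",
    "classify_nps",
    "classify_ps",
    "load_zones",
    "dump_zones",
]


class Zone(enum.IntEnum):
    """Homology zones ordered from strictest to loosest."""

    SAFE = 0
    TWILIGHT1 = 1
    TWILIGHT2 = 2
    DARK = 3

    def __str__(self) -> str:  # stable lowercase names for TSV/config output
        return {Zone.SAFE: "safe", Zone.TWILIGHT1: "twilight1",
                Zone.TWILIGHT2: "twilight2", Zone.DARK: "dark"}[self]

    @classmethod
    def from_name(cls, name: str) -> "Zone":
        return {"safe": cls.SAFE, "twilight1": cls.TWILIGHT1,
                "twilight2": cls.TWILIGHT2, "dark": cls.DARK}[name.lower()]


@dataclass(frozen=True)
class PSStats:
    """Partner-specific alignment statistics for a homo-interolog A'-B'.

    ``avg_log_eval`` / ``avg_positive`` / ``avg_log_lal`` are arithmetic
    means over the A-A' and B-B' alignments; ``frac_aa`` and ``frac_bb``
    are the combined length fractions (product of LAL/len(A) and
    LAL/len(A'), likewise for B) on the 0-1 scale.
    """

    avg_log_eval: float
    avg_positive: float
    frac_aa: float
    frac_bb: float
    avg_log_lal: float = float("nan")


@dataclass(frozen=True)
class ZoneThresholds:
    """One zone row: all conditions are inclusive (<= / >=) as published.

    NPS rows constrain (log_eval, positive, log_lal); PS rows constrain
    (log_eval, positive, frac_aa, frac_bb) with fraction thresholds stated
    in percent and compared against the 0-1 fractions x 100.
    """

    zone: Zone
    max_log_eval: float
    min_positive: float
    min_log_lal: Optional[float] = None
    min_frac_aa: Optional[float] = None  # percent
    min_frac_bb: Optional[float] = None  # percent

    def admits_nps(self, stats: AlignmentStats) -> bool:
        return (stats.log_eval <= self.max_log_eval
                and stats.positive_score >= self.min_positive
                and stats.log_lal >= self.min_log_lal)

    def admits_ps(self, stats: PSStats) -> bool:
        return (stats.avg_log_eval <= self.max_log_eval
                and stats.avg_positive >= self.min_positive
                and 100.0 * stats.frac_aa >= self.min_frac_aa
                and 100.0 * stats.frac_bb >= self.min_frac_bb)


#: Default NPS zone boundaries (derived from transient-dimer conservation
#: analysis; deliberately conservative, can be relaxed for obligate queries).
NPS_ZONES: tuple[ZoneThresholds, ...] = (
    ZoneThresholds(Zone.SAFE, max_log_eval=-100.0, min_positive=80.0, min_log_lal=5.2),
    ZoneThresholds(Zone.TWILIGHT1, max_log_eval=-50.0, min_positive=65.0, min_log_lal=4.0),
    ZoneThresholds(Zone.TWILIGHT2, max_log_eval=1.0, min_positive=60.0, min_log_lal=4.0),
    ZoneThresholds(Zone.DARK, max_log_eval=1.0, min_positive=0.0, min_log_lal=0.0),
)

#: Default PS zone boundaries over homo-interolog statistics.
PS_ZONES: tuple[ZoneThresholds, ...] = (
    ZoneThresholds(Zone.SAFE, max_log_eval=-100.0, min_positive=70.0,
                   min_frac_aa=80.0, min_frac_bb=80.0),
    ZoneThresholds(Zone.TWILIGHT1, max_log_eval=-50.0, min_positive=60.0,
                   min_frac_aa=60.0, min_frac_bb=60.0),
    ZoneThresholds(Zone.TWILIGHT2, max_log_eval=1.0, min_positive=55.0,
                   min_frac_aa=40.0, min_frac_bb=40.0),
    ZoneThresholds(Zone.DARK, max_log_eval=1.0, min_positive=0.0,
                   min_frac_aa=0.0, min_frac_bb=0.0),
)

#: BLASTP search cutoff EVal <= 10 on the natural-log scale.
SEARCH_LOG_EVAL_CUTOFF = math.log(10.0)


def classify_nps(stats: AlignmentStats,
                 zones: tuple[ZoneThresholds, ...] = NPS_ZONES) -> Optional[Zone]:
    """Strictest zone whose three NPS conditions all hold, or None."""
    for row in zones:
        if row.admits_nps(stats):
            return row.zone
    return None


def classify_ps(stats: PSStats,
                zones: tuple[ZoneThresholds, ...] = PS_ZONES) -> Optional[Zone]:
    """Strictest zone whose four PS conditions all hold, or None."""
    for row in zones:
        if row.admits_ps(stats):
            return row.zone
    return None


def dump_zones(zones: tuple[ZoneThresholds, ...], kind: str) -> str:
    """Serialise zone rows as YAML (the CLI override format)."""
    rows = []
    for z in zones:
        row = {"zone": str(z.zone), "max_log_eval": z.max_log_eval,
               "min_positive": z.min_positive}
        if kind == "nps":
            row["min_log_lal"] = z.min_log_lal
        else:
            row["min_frac_aa"] = z.min_frac_aa
            row["min_frac_bb"] = z.min_frac_bb
        rows.append(row)
    return yaml.safe_dump({"kind": kind, "zones": rows}, sort_keys=False)


def load_zones(text: str) -> tuple[ZoneThresholds, ...]:
    """Load zone rows from YAML produced by :func:`dump_zones`."""
    doc = yaml.safe_load(text)
    kind = doc["kind"]
    rows = []
    for row in doc["zones"]:
        if kind == "nps":
            rows.append(ZoneThresholds(Zone.from_name(row["zone"]),
                                       float(row["max_log_eval"]),
                                       float(row["min_positive"]),
                                       min_log_lal=float(row["min_log_lal"])))
        else:
            rows.append(ZoneThresholds(Zone.from_name(row["zone"]),
                                       float(row["max_log_eval"]),
                                       float(row["min_positive"]),
                                       min_frac_aa=float(row["min_frac_aa"]),
                                       min_frac_bb=float(row["min_frac_bb"])))
    rows.sort(key=lambda r: r.zone)
    return tuple(rows)
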