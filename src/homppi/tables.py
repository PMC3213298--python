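"""Plain-text tables shared by the predictors and the CLI.

The template annotation table is a TSV with one row per (template chain,
partner) holding the chain's metadata and its interface-label track as a
``0/1/?`` string.  ``partner_id`` is ``*`` for the non-partner-specific
union track, or the id of the specific partner chain for PS labels.
The complex-index TSV records which template chains co-occur and interact
within one solved complex.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable, TextIO

import pandas as pd

from homppi.structure_interface import LabelTrack

if TYPE_CHECKING:
    from homppi.nps_predictor import TemplateChain

TEMPLATE_COLUMNS = ["template_id", "partner_id", "species", "method",
                    "resolution", "complex_id", "sequence", "labels"]


def write_template_table(templates: Iterable["TemplateChain"], stream: TextIO) -> None:
    rows = [{
        "template_id": t.template_id,
        "partner_id": t.partner_id or "*",
        "species": t.species,
        "method": t.method,
        "resolution": "" if t.resolution is None else t.resolution,
        "complex_id": t.complex_id or "",
        "sequence": t.sequence,
        "labels": t.labels.labels,
    } for t in templates]
    pd.DataFrame(rows, columns=TEMPLATE_COLUMNS).to_csv(stream, sep="\t", index=False)


def read_template_table(stream: TextIO) -> list["TemplateChain"]:
    from homppi.nps_predictor import TemplateChain

    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    missing = set(TEMPLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"template table is missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(TemplateChain(
            template_id=row.template_id,
            sequence=row.sequence,
            labels=LabelTrack(row.labels),
            species=row.species,
            method=row.method,
            resolution=float(row.resolution) if row.resolution else None,
            complex_id=row.complex_id or None,
            partner_id=None if row.partner_id == "*" else row.partner_id,
        ))
    return out


def write_complex_index(pairs: Iterable[tuple[str, str, str]], stream: TextIO) -> None:
    """Rows of (complex_id, chain_id, comma-joined partner chain ids)."""
    stream.write("complex_id\tchain_id\tpartners\n")
    for complex_id, chain_id, partners in pairs:
        stream.write(f"{complex_id}\t{chain_id}\t{partners}\n")


def read_complex_index(stream: TextIO):
    from homppi.ps_predictor import ComplexIndex

    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    idx = ComplexIndex()
    for row in df.itertuples(index=False):
        for partner in filter(None, row.partners.split(",")):
            idx.add_interaction(row.complex_id, row.chain_id, partner)
    return idx
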