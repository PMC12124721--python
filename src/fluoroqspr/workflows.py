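"""End-to-end analysis workflows tying the pipeline stages together.

These functions reproduce the study-level fits once the externally computed
(DFT) descriptor tables are supplied as CSV: the two-descriptor logD model on
{#F, 1/q_S}, the analogous pKa model for the thioether series, and the
sulfone oxygen-charge/logD correlation.  They also provide the full
exhaustive search at the study's scale on synthetic data.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .compound_library import library_table, load_library
from .descriptor_engine import (
    DescriptorTable,
    expand_transforms,
    ingest_dft_descriptors,
    scale_minmax,
)
from .model_search import (
    CandidateModel,
    SearchReport,
    correlate,
    enumerate_models,
    fit_fixed_terms,
)
from .synthetic_data import paper_like_table

CONSTITUTIONAL_COLS = ("n_atoms", "n_heavy", "#F", "MW", "TPSA")
TWO_DESCRIPTOR_TERMS = ("#F", "1/q_S")


def assemble_full_table(dft_csv: str | Path) -> DescriptorTable:
    """Constitutional + ingested DFT descriptors, transform-expanded (unscaled)."""
    compounds = load_library()
    base = DescriptorTable(
        library_table(compounds),
        provenance={c: "constitutional" for c in CONSTITUTIONAL_COLS},
    )
    merged = ingest_dft_descriptors(dft_csv, base)
    return expand_transforms(merged)


def _experimental_series(attr: str) -> pd.Series:
    compounds = load_library()
    return pd.Series({c.id: getattr(c, attr) for c in compounds}, dtype=float)


def _scaled_subset(table: DescriptorTable, response: pd.Series) -> tuple[DescriptorTable, pd.Series]:
    """Restrict to compounds with a measured response, then min-max scale."""
    response = response.reindex(table.values.index)
    keep = response.notna()
    sub = DescriptorTable(
        table.values.loc[keep].copy(),
        provenance=dict(table.provenance),
        parents=dict(table.parents),
    )
    return scale_minmax(sub), response[keep]


def fit_logd_two_descriptor(dft_csv: str | Path) -> tuple[CandidateModel, int]:
    """Refit logD(7.4) ~ #F + 1/q_S over the measured compounds.

    Returns the fitted model and the number of compounds used.
    """
    table = assemble_full_table(dft_csv)
    scaled, y = _scaled_subset(table, _experimental_series("logd_exp"))
    return fit_fixed_terms(scaled, y, TWO_DESCRIPTOR_TERMS), len(y)


def fit_pka_two_descriptor(dft_csv: str | Path) -> tuple[CandidateModel, int]:
    """Refit conjugate-acid pKa ~ #F + 1/q_S over the thioether series."""
    table = assemble_full_table(dft_csv)
    scaled, y = _scaled_subset(table, _experimental_series("pka_exp"))
    return fit_fixed_terms(scaled, y, TWO_DESCRIPTOR_TERMS), len(y)


def sulfone_oxygen_logd_correlation(dft_csv: str | Path) -> tuple[float, int]:
    """Squared Pearson correlation of sulfone q_O with measured logD(7.4)."""
    compounds = load_library()
    table = assemble_full_table(dft_csv)
    ids = [
        c.id for c in compounds
        if c.sulfur_state == "sulfone" and c.logd_exp is not None
        and c.id in set(table.values.index)
    ]
    q_o = table.values.loc[ids, "q_O"].to_numpy()
    logd = pd.Series({c.id: c.logd_exp for c in compounds}).loc[ids].to_numpy()
    _, r2 = correlate(q_o, logd)
    return r2, len(ids)


def search_at_study_scale(seed: int) -> SearchReport:
    """Exhaustive 1-/2-descriptor search on a synthetic table at the study's
    scale (20 compounds, descriptor set expanding to 220 columns)."""
    table, y, _ = paper_like_table(seed)
    scaled = scale_minmax(expand_transforms(table))
    return enumerate_models(scaled, y)
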