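"""Seeded generators for every input the pipeline consumes.

Each generator records its ground truth so the corresponding reduction stage
can be round-tripped: noiseless output is inverted exactly, noisy output is
recovered within stated statistical tolerances.  All randomness flows through
``numpy.random.default_rng(seed)``; identical inputs give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptor_engine import DescriptorTable
from .nmr_reduction import PartitionMeasurement, TitrationSeries, _sigmoid

#: per-kind sampling used for synthetic descriptor columns; ranges chosen so
#: the transform-validity paths (inverse, log) are all exercised.
COLUMN_KINDS = ("normal", "charge", "energy", "volume", "count")
KIND_SPECS = {
    "normal": ("normal", 0.0, 1.0),
    "charge": ("uniform", -0.7, 0.3),
    "energy": ("uniform", -12.0, -1.0),
    "volume": ("uniform", 80.0, 400.0),
    "count": ("integers", 0, 5),
}


@dataclass(frozen=True)
class PlantedLaw:
    term_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.term_names) != len(self.coefficients):
            raise ValueError("term_names and coefficients must align")


def _draw_column(rng: np.random.Generator, kind: str, n: int) -> np.ndarray:
    dist, a, b = KIND_SPECS[kind]
    if dist == "normal":
        return rng.normal(a, b, n)
    if dist == "uniform":
        return rng.uniform(a, b, n)
    return rng.integers(a, b + 1, n).astype(float)


def gen_descriptor_table(
    n_compounds: int, n_descriptors: int, law: PlantedLaw
) -> tuple[DescriptorTable, pd.Series, dict]:
    """Synthetic compounds x descriptors table with a planted linear response.

    Returns the (unscaled) table, the noisy response and a truth record
    holding the law, the per-column distributions and the noiseless response.
    """
    if n_compounds < 8:
        raise ValueError("need at least 8 compounds")
    if n_descriptors < 3:
        raise ValueError("need at least 3 descriptors")
    rng = np.random.default_rng(law.seed)
    names = [f"d{i:03d}" for i in range(n_descriptors)]
    missing = [t for t in law.term_names if t not in names]
    if missing:
        raise ValueError(f"law references missing column(s) {missing!r}")
    kinds = {name: COLUMN_KINDS[i % len(COLUMN_KINDS)] for i, name in enumerate(names)}
    data = {name: _draw_column(rng, kinds[name], n_compounds) for name in names}
    ids = [f"c{i:02d}" for i in range(n_compounds)]
    values = pd.DataFrame(data, index=ids)
    values.index.name = "compound_id"
    y0 = np.full(n_compounds, law.intercept, dtype=float)
    for term, coef in zip(law.term_names, law.coefficients):
        y0 = y0 + coef * values[term].to_numpy()
    y = y0 + rng.normal(0.0, 1.0, n_compounds) * law.noise_sd
    table = DescriptorTable(
        values, provenance={c: "dft_ingested" for c in values.columns}
    )
    truth = {
        "law": law,
        "distributions": {c: KIND_SPECS[kinds[c]] for c in names},
        "response_noiseless": pd.Series(y0, index=ids),
    }
    return table, pd.Series(y, index=ids, name="response"), truth


def paper_like_table(
    seed: int,
    n_compounds: int = 20,
    n_base: int = 44,
    target_r2: float = 0.95,
) -> tuple[DescriptorTable, pd.Series, dict]:
    """Preset emulating the study's scale: 20 compounds and a descriptor set
    that expands to ~220 columns (every base column admits all four
    transforms), with a planted 2-term law whose noise is set for the target
    in-sample R^2.
    """
    rng = np.random.default_rng(seed)
    names = [f"b{i:03d}" for i in range(n_base)]
    ids = [f"c{i:02d}" for i in range(n_compounds)]
    data = {}
    for name in names:
        lo = rng.uniform(0.05, 5.0)
        width = rng.uniform(0.5, 10.0)
        data[name] = rng.uniform(lo, lo + width, n_compounds)
    values = pd.DataFrame(data, index=ids)
    values.index.name = "compound_id"
    terms = (names[0], names[1])
    coefficients = (
        1.0 / values[terms[0]].std(),
        0.5 / values[terms[1]].std(),
    )
    y0 = coefficients[0] * values[terms[0]] + coefficients[1] * values[terms[1]] + 1.0
    var_signal = float(np.var(y0.to_numpy()))
    noise_sd = float(np.sqrt(var_signal * (1.0 / target_r2 - 1.0)))
    y = y0 + rng.normal(0.0, noise_sd, n_compounds)
    table = DescriptorTable(
        values, provenance={c: "dft_ingested" for c in values.columns}
    )
    truth = {
        "terms": terms,
        "coefficients": coefficients,
        "intercept": 1.0,
        "noise_sd": noise_sd,
        "response_noiseless": y0,
    }
    return table, pd.Series(y.to_numpy(), index=ids, name="response"), truth


def gen_partition(
    true_logd: float,
    standard_logd: float,
    noise_cv: float,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[PartitionMeasurement]:
    """Integrals consistent with the double-ratio identity, then multiplicative
    log-normal noise of coefficient of variation ``noise_cv`` per integral."""
    if not 0.0 <= noise_cv <= 0.2:
        raise ValueError("noise_cv must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    ratio = 10.0 ** (true_logd - standard_logd)
    out = []
    for rep in range(n_replicates):
        tube_oct = rng.uniform(0.5, 2.0)   # per-phase spectrometer gauge
        tube_aq = rng.uniform(0.5, 2.0)
        conc = rng.uniform(0.5, 2.0)       # analyte loading
        ideal = {
            "standard_integral_oct": tube_oct,
            "analyte_integral_oct": tube_oct * conc * ratio,
            "standard_integral_aq": tube_aq,
            "analyte_integral_aq": tube_aq * conc,
        }
        noisy = {
            k: v * float(np.exp(noise_cv * rng.standard_normal()))
            for k, v in ideal.items()
        }
        out.append(
            PartitionMeasurement(
                standard_logd=standard_logd, replicate_id=rep, **noisy
            )
        )
    return out


def gen_titration(
    true_pka: float,
    shift_acid: float,
    shift_base: float,
    ph_grid: np.ndarray | list[float],
    noise_sd: float,
    seed: int = 0,
    nucleus: str = "19F",
) -> tuple[TitrationSeries, dict]:
    """Henderson-Hasselbalch sigmoid shifts + Gaussian noise on a pH grid."""
    ph = np.asarray(ph_grid, dtype=float)
    rng = np.random.default_rng(seed)
    if ph.min() > true_pka - 2 or ph.max() < true_pka + 2:
        warnings.warn(
            "pH grid does not span pKa +/- 2: the fit may be unstable"
        )
    shift = _sigmoid(ph, true_pka, shift_acid, shift_base)
    shift = shift + rng.normal(0.0, 1.0, len(ph)) * noise_sd
    series = TitrationSeries(
        points=tuple(zip(ph.tolist(), shift.tolist())), nucleus=nucleus
    )
    truth = {
        "pka": true_pka,
        "shift_acid": shift_acid,
        "shift_base": shift_base,
        "noise_sd": noise_sd,
    }
    return series, truth
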