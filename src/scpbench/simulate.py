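"""Synthetic DIA-style data with known ground truth.

Emulates the statistical structure the benchmarking analyses assume:

* protein base abundances log-normal over >= 4 orders of magnitude;
* technical noise multiplicative log-normal with a CV that decays
  exponentially from ~35% at the limit of quantification to ~5% for abundant
  proteins;
* missingness missing-not-at-random: detection probability is logistic in
  log2 abundance;
* two-proteome mixes where each species' proteins scale by its mass ratio
  between conditions, so expected fold changes are known exactly;
* single-cell matrices with two or more cell types, volume-proportional
  (diameter cubed) per-cell scaling, extra cell-to-cell biological
  variability, designated differential proteins, and blank control wells.

Every generator returns a ``SimulationTruth`` sufficient to recompute the
expected values exactly, and is byte-deterministic under its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .benchmark import MixDesign
from .io import Origin, ProteinRecord, ProteomeDB, QuantMatrix, QuantReport, SPECIES_SUFFIXES

__all__ = [
    "NoiseModel",
    "DropoutModel",
    "SimulationTruth",
    "simulate_proteome",
    "simulate_mix",
    "simulate_cells",
    "DEFAULT_RESIDUE_FREQS",
    "HELA_YEAST_MIXES",
]

#: average amino-acid frequencies of reviewed UniProt entries (percent/100)
DEFAULT_RESIDUE_FREQS: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: the three HeLa:yeast mix compositions (pg) used for accuracy benchmarking
HELA_YEAST_MIXES = MixDesign(
    conditions={
        "mix_150_100": {"human": 150.0, "yeast": 100.0},
        "mix_200_50": {"human": 200.0, "yeast": 50.0},
        "mix_240_10": {"human": 240.0, "yeast": 10.0},
    }
)

#: log10 mean/SD of base protein abundance (arbitrary intensity units);
#: SD 0.8 spans >= 4 orders of magnitude over a realistically sized proteome
BASE_LOG10_MEAN = 4.0
BASE_LOG10_SD = 0.8


@dataclass(frozen=True)
class NoiseModel:
    """Abundance-dependent technical CV.

    ``cv(a) = cv_min + (cv_max - cv_min) * exp(-k * max(0, log10(a) - a0))``:
    the CV sits at ``cv_max`` at the limit of quantification (log10 abundance
    ``a0``) and decays exponentially to ``cv_min`` for abundant proteins.
    """

    cv_min: float = 0.05
    cv_max: float = 0.35
    decay_rate: float = 1.0
    ref_log10_abundance: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.cv_min <= self.cv_max:
            raise ValueError("need 0 <= cv_min <= cv_max")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be > 0")

    def cv(self, abundance):
        a = np.asarray(abundance, dtype=float)
        excess = np.maximum(0.0, np.log10(a) - self.ref_log10_abundance)
        return self.cv_min + (self.cv_max - self.cv_min) * np.exp(-self.decay_rate * excess)

    def sigma(self, abundance):
        """Log-normal shape parameter giving the target CV."""
        return np.sqrt(np.log1p(np.square(self.cv(abundance))))


@dataclass(frozen=True)
class DropoutModel:
    """Missing-not-at-random detection: logistic in log2 abundance.

    ``P(detect | a) = 1 / (1 + exp(-(log2 a - midpoint) / steepness))``.
    The default midpoint (log2 of abundance 100) coincides with the noise
    model's limit of quantification.
    """

    midpoint: float = 6.64
    steepness: float = 1.0

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")

    def detect_prob(self, abundance):
        a = np.asarray(abundance, dtype=float)
        with np.errstate(divide="ignore"):
            z = (np.log2(a) - self.midpoint) / self.steepness
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class SimulationTruth:
    """Ground truth serialized alongside every generated dataset."""

    proteins: pd.DataFrame            # per-protein base abundance, species, effects
    multipliers: dict = field(default_factory=dict)   # condition -> species -> factor
    noise: NoiseModel = field(default_factory=NoiseModel)
    dropout: DropoutModel = field(default_factory=DropoutModel)
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def expected_fc(self, species: str, cond_a: str, cond_b: str) -> float:
        return self.multipliers[cond_a][species] / self.multipliers[cond_b][species]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "proteins": self.proteins.reset_index().to_dict(orient="list"),
            "multipliers": self.multipliers,
            "noise": self.noise.__dict__,
            "dropout": self.dropout.__dict__,
            "seed": self.seed,
            "extra": self.extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        proteins = pd.DataFrame(payload["proteins"]).set_index("protein_id")
        return cls(
            proteins=proteins,
            multipliers=payload["multipliers"],
            noise=NoiseModel(**payload["noise"]),
            dropout=DropoutModel(**payload["dropout"]),
            seed=payload["seed"],
            extra=payload.get("extra", {}),
        )


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------

def simulate_proteome(
    n_proteins: int,
    length_dist: int | tuple | Sequence[int] = ("lognormal", 380, 0.45),
    residue_freqs: Mapping[str, float] | None = None,
    seed: int = 0,
    accession_prefix: str = "SYN",
) -> ProteomeDB:
    """Generate random protein sequences with given residue frequencies.

    ``length_dist`` is a fixed integer length, an explicit length per protein,
    or ``("lognormal", median, sigma)`` (minimum length 30). Residue
    frequencies must be a proper distribution with nonzero K and R so the
    sequences are digestible.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    freqs = dict(residue_freqs or DEFAULT_RESIDUE_FREQS)
    residues = np.array(sorted(freqs))
    p = np.array([freqs[r] for r in residues], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("degenerate residue frequency vector")
    p = p / p.sum()
    if freqs.get("K", 0.0) <= 0 or freqs.get("R", 0.0) <= 0:
        raise ValueError("K and R frequencies must be nonzero")
    rng = np.random.default_rng(seed)
    if isinstance(length_dist, int):
        lengths = np.full(n_proteins, length_dist)
    elif isinstance(length_dist, tuple) and length_dist[0] == "lognormal":
        _, median, sigma = length_dist
        lengths = np.maximum(
            30, rng.lognormal(np.log(median), sigma, size=n_proteins).astype(int)
        )
    else:
        lengths = np.asarray(list(length_dist), dtype=int)
        if len(lengths) != n_proteins:
            raise ValueError("explicit length list must match n_proteins")
    records = []
    for i, ln in enumerate(lengths):
        seq = "".join(rng.choice(residues, size=int(ln), p=p))
        records.append(
            ProteinRecord(
                accession=f"{accession_prefix}{i:05d}",
                sequence=seq,
                description="synthetic protein",
                origin=Origin.TARGET,
            )
        )
    return ProteomeDB(records)


# ---------------------------------------------------------------------------
# Two-proteome mixes
# ---------------------------------------------------------------------------

_SUFFIX_BY_SPECIES = {sp: suf for suf, sp in SPECIES_SUFFIXES.items()}


def _accession(species: str, i: int) -> str:
    suffix = _SUFFIX_BY_SPECIES.get(species)
    if suffix is None:
        suffix = "_" + species.upper()
        SPECIES_SUFFIXES[suffix] = species  # register so pivoting resolves it
        _SUFFIX_BY_SPECIES[species] = suffix
    return f"P{i:05d}{suffix}"


def _draw_base_abundance(rng: np.random.Generator, n: int) -> np.ndarray:
    return 10.0 ** rng.normal(BASE_LOG10_MEAN, BASE_LOG10_SD, size=n)


def _draw_n_peptides(rng: np.random.Generator, base: np.ndarray) -> np.ndarray:
    # more abundant proteins are quantified from more peptides
    lam = np.clip(1.5 * (np.log10(base) - 1.5), 0.3, 25.0)
    return rng.poisson(lam) + 1


def _noisy_observation(
    rng: np.random.Generator, expected: np.ndarray, noise: NoiseModel
) -> np.ndarray:
    sigma = noise.sigma(expected)
    # mean-preserving multiplicative log-normal noise
    return expected * rng.lognormal(-0.5 * sigma**2, sigma)


def simulate_mix(
    design: MixDesign,
    n_proteins_per_species: Mapping[str, int] | int = 500,
    n_replicates: int = 3,
    noise: NoiseModel | None = NoiseModel(),
    dropout: DropoutModel | None = DropoutModel(),
    seed: int = 0,
) -> tuple[QuantReport, SimulationTruth]:
    """Simulate a DIA-style quant report for a two-proteome mix experiment.

    Each species' per-condition multiplier is its mass divided by that
    species' maximum mass across conditions, so base abundances are
    condition-agnostic and design ratios are recovered exactly in the
    noise-free limit. ``noise=None`` / ``dropout=None`` switch the respective
    effect off.
    """
    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    if isinstance(n_proteins_per_species, int):
        n_proteins_per_species = {sp: n_proteins_per_species for sp in design.species}
    rng = np.random.default_rng(seed)

    species_col, acc_col = [], []
    for sp in design.species:
        n = n_proteins_per_species[sp]
        species_col += [sp] * n
        acc_col += [_accession(sp, i) for i in range(n)]
    species_arr = np.array(species_col)
    base = _draw_base_abundance(rng, len(acc_col))
    n_pep = _draw_n_peptides(rng, base)

    multipliers = {
        cond: {
            sp: design.conditions[cond].get(sp, 0.0)
            / max(design.conditions[c].get(sp, 0.0) for c in design.conditions)
            for sp in design.species
        }
        for cond in design.conditions
    }

    rows = []
    for cond in design.conditions:
        mult = np.array([multipliers[cond][sp] for sp in species_arr])
        expected = base * mult
        for rep in range(1, n_replicates + 1):
            observed = (
                _noisy_observation(rng, expected, noise) if noise else expected.copy()
            )
            if dropout is not None:
                detected = rng.random(len(expected)) < dropout.detect_prob(expected)
            else:
                detected = expected > 0
            detected &= expected > 0
            run = f"{cond}_r{rep}"
            idx = np.flatnonzero(detected)
            rows.append(
                pd.DataFrame(
                    {
                        "run_id": run,
                        "condition": cond,
                        "replicate": rep,
                        "protein_group": np.array(acc_col)[idx],
                        "quantity": observed[idx],
                        "n_peptides": n_pep[idx],
                    }
                )
            )
    data = pd.concat(rows, ignore_index=True)
    report = QuantReport(data)
    truth = SimulationTruth(
        proteins=pd.DataFrame(
            {"species": species_arr, "base_abundance": base, "n_peptides": n_pep},
            index=pd.Index(acc_col, name="protein_id"),
        ),
        multipliers=multipliers,
        noise=noise or NoiseModel(cv_min=0.0, cv_max=0.0, decay_rate=1.0),
        dropout=dropout or DropoutModel(midpoint=-np.inf),
        seed=seed,
        extra={"n_replicates": n_replicates},
    )
    return report, truth


# ---------------------------------------------------------------------------
# Single-cell matrices
# ---------------------------------------------------------------------------

def simulate_cells(
    n_cells_per_type: Mapping[str, int],
    n_proteins: int = 1000,
    n_de_proteins: int = 50,
    effect_size_log2: float = 1.0,
    size_model: Mapping[str, tuple[float, float]] | None = None,
    blank_count: int = 3,
    noise: NoiseModel | None = NoiseModel(),
    dropout: DropoutModel | None = DropoutModel(),
    bio_cv: float = 0.5,
    background_fraction: float = 2e-4,
    reference_diameter_um: float = 20.0,
    seed: int = 0,
) -> tuple[QuantMatrix, pd.DataFrame, SimulationTruth]:
    """Simulate a single-cell protein quant matrix with blanks and known DE.

    Cell diameters are drawn per type from ``size_model`` (mean, SD in µm;
    default 20 ± 2.5 for every type) and the per-cell abundance scale is
    volume-proportional, ``(diameter / reference)^3``. The designated DE
    subset is shifted by ``effect_size_log2`` in the *second* cell type.
    Biological cell-to-cell variability is an extra log-normal factor with CV
    ``bio_cv`` on top of the technical noise. Blanks carry only a
    ``background_fraction`` of each protein's abundance, so almost everything
    drops out.
    """
    types = list(n_cells_per_type)
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    if n_de_proteins > n_proteins:
        raise ValueError("n_de_proteins exceeds n_proteins")
    size_model = size_model or {t: (20.0, 2.5) for t in types}
    rng = np.random.default_rng(seed)

    prot_ids = [f"P{i:05d}_HUMAN" for i in range(n_proteins)]
    base = _draw_base_abundance(rng, n_proteins)
    de_idx = rng.choice(n_proteins, size=n_de_proteins, replace=False)
    de_mask = np.zeros(n_proteins, dtype=bool)
    de_mask[de_idx] = True
    de_type = types[1]
    effect = np.where(de_mask, 2.0**effect_size_log2, 1.0)

    columns, col_meta, col_values = [], [], []

    def _simulate_column(expected: np.ndarray) -> np.ndarray:
        observed = _noisy_observation(rng, expected, noise) if noise else expected.copy()
        if dropout is not None:
            detected = rng.random(n_proteins) < dropout.detect_prob(expected)
        else:
            detected = expected > 0
        return np.where(detected & (expected > 0), observed, np.nan)

    for ctype in types:
        mean_um, sd_um = size_model[ctype]
        for j in range(n_cells_per_type[ctype]):
            diameter = max(5.0, rng.normal(mean_um, sd_um))
            scale = (diameter / reference_diameter_um) ** 3
            expected = base * scale * (effect if ctype == de_type else 1.0)
            if bio_cv > 0:
                s = np.sqrt(np.log1p(bio_cv**2))
                expected = expected * rng.lognormal(-0.5 * s**2, s, size=n_proteins)
            columns.append(f"{ctype}_c{j + 1:03d}")
            col_meta.append(
                {"cell_type": ctype, "cell_diameter_um": diameter, "is_blank": False}
            )
            col_values.append(_simulate_column(expected))
    for j in range(blank_count):
        columns.append(f"blank_{j + 1:02d}")
        col_meta.append({"cell_type": "blank", "cell_diameter_um": np.nan, "is_blank": True})
        col_values.append(_simulate_column(base * background_fraction))

    values = pd.DataFrame(
        np.column_stack(col_values),
        index=pd.Index(prot_ids, name="protein_id"),
        columns=pd.Index(columns, name="sample_id"),
    )
    annotation = pd.DataFrame(col_meta, index=values.columns)
    annotation["size_group"] = pd.cut(
        annotation["cell_diameter_um"],
        bins=[0.0, 20.0, 25.0, np.inf],
        labels=["15-20um", "20-25um", "25-30um"],
    )
    protein_meta = pd.DataFrame(
        {"species": "human", "is_de": de_mask}, index=values.index
    )
    matrix = QuantMatrix(values=values, sample_meta=annotation, protein_meta=protein_meta)
    truth = SimulationTruth(
        proteins=pd.DataFrame(
            {
                "base_abundance": base,
                "is_de": de_mask,
                "effect_log2": np.where(de_mask, effect_size_log2, 0.0),
            },
            index=values.index,
        ),
        multipliers={},
        noise=noise or NoiseModel(cv_min=0.0, cv_max=0.0, decay_rate=1.0),
        dropout=dropout or DropoutModel(midpoint=-np.inf),
        seed=seed,
        extra={
            "de_type": de_type,
            "bio_cv": bio_cv,
            "background_fraction": background_fraction,
            "reference_diameter_um": reference_diameter_um,
        },
    )
    return matrix, annotation, truth
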