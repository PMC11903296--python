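"""Two-proteome-mix quantitative accuracy and precision benchmarking.

Mixing two species' digests at known mass ratios makes the expected
between-sample fold change of every protein known a priori: each species'
proteins must shift together by the ratio of its masses in the two mixes.
Observed per-protein fold changes against expectation measure accuracy;
replicate CVs and a rolling-window "local CV" of fold changes across the
abundance range measure precision and how it degrades toward the limit of
quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import QuantMatrix

__all__ = [
    "MixDesign",
    "fold_change_table",
    "local_cv",
    "replicate_cv",
    "ReplicateCv",
    "completeness",
    "CompletenessProfile",
    "min_peptide_filter",
    "benchmark_report",
    "BenchmarkReport",
]


@dataclass(frozen=True)
class MixDesign:
    """Mass composition (pg) of each species per condition.

    Example: ``MixDesign({"mixA": {"human": 150, "yeast": 100},
    "mixB": {"human": 200, "yeast": 50}})``.
    """

    conditions: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("a mix design needs >= 2 conditions")
        for cond, masses in self.conditions.items():
            for sp, m in masses.items():
                if m < 0:
                    raise ValueError(f"negative mass for {sp} in {cond}")
        species = self.species
        if not any(
            len({self.conditions[c].get(sp, 0.0) for c in self.conditions}) > 1
            for sp in species
        ):
            raise ValueError("no species differs between conditions")

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for masses in self.conditions.values():
            for sp in masses:
                if sp not in out:
                    out.append(sp)
        return out

    def expected_fc(self, species: str, cond_a: str, cond_b: str) -> float:
        """Expected linear fold change (condition a over b) for a species."""
        try:
            mass_a = self.conditions[cond_a][species]
            mass_b = self.conditions[cond_b][species]
        except KeyError as exc:
            raise KeyError(f"species/condition absent from design: {exc}") from exc
        if mass_b == 0:
            raise ZeroDivisionError(f"{species} mass in {cond_b} is zero")
        return mass_a / mass_b

    @classmethod
    def from_dict(cls, payload: Mapping) -> "MixDesign":
        return cls(conditions={c: dict(m) for c, m in payload["conditions"].items()})


def _condition_means(matrix: QuantMatrix, condition: str) -> pd.Series:
    cols = matrix.samples_for(condition)
    return matrix.values[cols].mean(axis=1, skipna=True)


def fold_change_table(matrix: QuantMatrix, cond_a: str, cond_b: str) -> pd.DataFrame:
    """Per-protein fold changes between two conditions.

    Means are taken over the observed replicates of each condition on raw
    linear quantities; a protein enters the table only if it was observed at
    least once in both conditions and both means are positive. Columns:
    protein_id (index), species, mean_a, mean_b, log2_avg_abundance, log2_fc,
    n_peptides. The number of excluded proteins is in ``df.attrs['n_excluded']``.
    """
    mean_a = _condition_means(matrix, cond_a)
    mean_b = _condition_means(matrix, cond_b)
    ok = mean_a.notna() & mean_b.notna() & (mean_a > 0) & (mean_b > 0)
    df = pd.DataFrame(
        {
            "species": matrix.protein_meta.get(
                "species", pd.Series(index=matrix.values.index, dtype=object)
            ),
            "mean_a": mean_a,
            "mean_b": mean_b,
        }
    )[ok]
    df["log2_avg_abundance"] = np.log2((df["mean_a"] + df["mean_b"]) / 2.0)
    df["log2_fc"] = np.log2(df["mean_a"] / df["mean_b"])
    if "n_peptides" in matrix.protein_meta.columns:
        df["n_peptides"] = matrix.protein_meta.loc[df.index, "n_peptides"]
    df.attrs["n_excluded"] = int((~ok).sum())
    df.attrs["conditions"] = (cond_a, cond_b)
    return df


def local_cv(rows: pd.DataFrame, window_size: int = 100, scale: str = "linear") -> pd.DataFrame:
    """Rolling-window CV of fold changes over the abundance range.

    Rows are ordered by ``log2_avg_abundance`` (descending); within each
    window of ``window_size`` proteins the CV (sample SD over mean, percent)
    of the linear-scale ratios ``2**log2_fc`` is computed (``scale='log2'``
    computes it on the log2 fold changes instead). Windows step one protein
    at a time and lie fully inside the range; with fewer rows than the window
    a single window spans everything. Returns a frame with columns
    ``center_log2_abundance`` and ``cv_percent``.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if len(rows) < 2:
        raise ValueError("need >= 2 fold-change rows")
    ordered = rows.sort_values("log2_avg_abundance", ascending=False)
    if scale == "linear":
        series = np.exp2(ordered["log2_fc"])
    elif scale == "log2":
        series = ordered["log2_fc"]
    else:
        raise ValueError(f"unknown scale {scale!r}")
    w = min(window_size, len(ordered))
    roll = series.rolling(window=w)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * roll.std(ddof=1) / roll.mean()
    centers = ordered["log2_avg_abundance"].rolling(window=w).mean()
    out = pd.DataFrame(
        {"center_log2_abundance": centers, "cv_percent": cv.abs()}
    ).dropna().reset_index(drop=True)
    out.attrs["window_size"] = w
    return out


@dataclass(frozen=True)
class ReplicateCv:
    """Per-protein replicate CVs (%) within one condition and their median."""

    per_protein: pd.Series
    median: float
    n_excluded: int


def replicate_cv(matrix: QuantMatrix, condition: str) -> ReplicateCv:
    """Technical-replicate CV per protein on raw quantities.

    A protein needs >= 2 observed values within the condition; others are
    excluded from the median.
    """
    cols = matrix.samples_for(condition)
    if len(cols) < 2:
        raise ValueError(f"condition {condition!r} has < 2 replicates")
    sub = matrix.values[cols]
    n_obs = sub.notna().sum(axis=1)
    eligible = sub[n_obs >= 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * eligible.std(axis=1, ddof=1, skipna=True) / eligible.mean(
            axis=1, skipna=True
        )
    cv = cv.dropna()
    return ReplicateCv(
        per_protein=cv,
        median=float(cv.median()) if len(cv) else float("nan"),
        n_excluded=int((n_obs < 2).sum()),
    )


@dataclass(frozen=True)
class CompletenessProfile:
    """How consistently proteins are observed across files."""

    per_protein_files: pd.Series       # observed-file count per protein
    in_all_fraction: float             # fraction of proteins seen in every file
    cumulative: pd.Series              # proteins observed in >= k files, k = 1..n

    @property
    def n_files(self) -> int:
        return int(self.cumulative.index.max())


def completeness(matrix: QuantMatrix) -> CompletenessProfile:
    """Data-completeness profile of a quant matrix (observed cells only)."""
    if matrix.values.shape[1] == 0 or matrix.values.shape[0] == 0:
        raise ValueError("empty matrix")
    counts = matrix.observed.sum(axis=1)
    n = matrix.values.shape[1]
    ks = np.arange(1, n + 1)
    cumulative = pd.Series(
        [(counts >= k).sum() for k in ks], index=pd.Index(ks, name="min_files")
    )
    return CompletenessProfile(
        per_protein_files=counts,
        in_all_fraction=float((counts == n).mean()),
        cumulative=cumulative,
    )


def min_peptide_filter(rows: pd.DataFrame, min_peptides: int = 2) -> pd.DataFrame:
    """Drop proteins quantified with fewer than ``min_peptides`` peptides.

    The removal fraction is in ``out.attrs['removed_fraction']``.
    """
    if "n_peptides" not in rows.columns:
        raise KeyError("fold-change rows carry no n_peptides column")
    keep = rows["n_peptides"] >= min_peptides
    out = rows[keep].copy()
    out.attrs.update(rows.attrs)
    out.attrs["removed_fraction"] = float((~keep).mean()) if len(rows) else 0.0
    return out


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-species accuracy summary plus the Bland–Altman coordinates."""

    species_summary: pd.DataFrame   # expected_fc, median_observed_fc, bias, n
    bland_altman: pd.DataFrame      # x = log2_avg_abundance, y = log2_fc, species
    fc_table: pd.DataFrame
    conditions: tuple[str, str] = field(default=("a", "b"))


def benchmark_report(
    matrix: QuantMatrix,
    design: MixDesign,
    cond_a: str,
    cond_b: str,
    min_peptides: int | None = None,
) -> BenchmarkReport:
    """Accuracy summary of a two-proteome mix comparison.

    For each species the median observed linear fold change is compared with
    the expected fold change from the design's mass ratios; bias is their
    ratio (1.0 = perfect recovery). Also emits the Bland–Altman table
    (log2 average abundance vs log2 fold change per protein).
    """
    fc = fold_change_table(matrix, cond_a, cond_b)
    if min_peptides is not None:
        fc = min_peptide_filter(fc, min_peptides)
    unknown = set(fc["species"].dropna().unique()) - set(design.species)
    if unknown:
        raise KeyError(f"species not in mix design: {sorted(unknown)}")
    if fc["species"].isna().any():
        raise KeyError("proteins with unresolvable species present")
    rows = []
    for sp, grp in fc.groupby("species", sort=True):
        expected = design.expected_fc(sp, cond_a, cond_b)
        observed = float(np.exp2(grp["log2_fc"]).median())
        rows.append(
            {
                "species": sp,
                "n_proteins": len(grp),
                "expected_fc": expected,
                "median_observed_fc": observed,
                "bias": observed / expected,
            }
        )
    summary = pd.DataFrame(rows).set_index("species")
    ba = fc[["log2_avg_abundance", "log2_fc", "species"]].copy()
    return BenchmarkReport(
        species_summary=summary, bland_altman=ba, fc_table=fc, conditions=(cond_a, cond_b)
    )
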