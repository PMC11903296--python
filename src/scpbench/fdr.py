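"""Entrapment-based FDR validation.

A search engine's reported FDR can be checked empirically by appending, to the
target database, sequences known to be absent from the sample: either a
shuffled copy of the target (residues permuted per protein while every K, R
and P stays in place, so tryptic peptide boundaries, lengths and masses are
preserved) or a foreign-species proteome. Any hit to those entries is a false
positive, and the empirical FDR is estimated as

    FDR_hat = d * (1 + 1/r) / (t + d)

where ``d`` counts decoy/entrapment protein hits, ``t`` target protein hits,
and ``r`` is the decoy-to-target database size ratio. The ``1/r`` term
accounts for false hits that land in the target database rather than the
decoy part of the search space.

This module generates shuffled databases, digests proteomes in silico to
quantify peptide-space overlap (a valid entrapment shares essentially no
peptides with the target), estimates FDR from labeled hit sets, and contrasts
per-replicate FDR against the FDR of the union of replicate hits — pooling
unique IDs across replicates accumulates false positives, which is why mean
per-replicate ID counts are the honest summary.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Origin, ProteinRecord, ProteomeDB

__all__ = [
    "DigestSpec",
    "digest",
    "PeptideIndex",
    "build_peptide_index",
    "OverlapSummary",
    "peptide_overlap",
    "shuffle_database",
    "FdrEstimate",
    "estimate_fdr",
    "accumulated_fdr",
    "simulate_entrapment_search",
]

DEFAULT_FIXED_RESIDUES = frozenset("KRP")

#: cleavage-site regex per enzyme: trypsin cuts C-terminal of K/R but not
#: before proline; trypsin/P ignores the proline rule
_CLEAVAGE_PATTERNS = {
    "trypsin": re.compile(r"[KR](?!P)"),
    "trypsin/P": re.compile(r"[KR]"),
}


@dataclass(frozen=True)
class DigestSpec:
    """In-silico digestion parameters."""

    enzyme: str = "trypsin"
    missed_cleavages: int = 0
    min_len: int = 7
    max_len: int = 30
    equate_il: bool = False

    def __post_init__(self) -> None:
        if self.enzyme not in _CLEAVAGE_PATTERNS:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


def digest(record: ProteinRecord | str, spec: DigestSpec = DigestSpec()) -> list[str]:
    """Cleave a protein into tryptic peptides, in sequence order.

    Cleaves after K/R (suppressed before P unless enzyme is trypsin/P), emits
    peptides with up to ``spec.missed_cleavages`` internal sites, and applies
    the length filter last.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if not seq:
        return []
    pattern = _CLEAVAGE_PATTERNS[spec.enzyme]
    cuts = [0] + [m.end() for m in pattern.finditer(seq) if m.end() < len(seq)] + [len(seq)]
    peptides: list[str] = []
    n_seg = len(cuts) - 1
    for i in range(n_seg):
        for mc in range(spec.missed_cleavages + 1):
            j = i + mc + 1
            if j > n_seg:
                break
            pep = seq[cuts[i]:cuts[j]]
            if spec.min_len <= len(pep) <= spec.max_len:
                peptides.append(pep)
    if spec.equate_il:
        peptides = [p.replace("I", "L") for p in peptides]
    return peptides


@dataclass
class PeptideIndex:
    """Unique-peptide set of a database under a fixed digestion spec."""

    origin: Origin
    peptides: frozenset[str]
    spec: DigestSpec = field(default_factory=DigestSpec)

    def __len__(self) -> int:
        return len(self.peptides)


def build_peptide_index(db: ProteomeDB, spec: DigestSpec = DigestSpec(),
                        origin: Origin | None = None) -> PeptideIndex:
    """Digest every protein and pool unique peptides (set semantics)."""
    peps: set[str] = set()
    origins = {rec.origin for rec in db}
    for rec in db:
        peps.update(digest(rec, spec))
    if origin is None:
        origin = origins.pop() if len(origins) == 1 else Origin.TARGET
    return PeptideIndex(origin=origin, peptides=frozenset(peps), spec=spec)


@dataclass(frozen=True)
class OverlapSummary:
    """Venn-style overlap of two unique-peptide sets."""

    shared: int
    only_a: int
    only_b: int
    shared_percent: float  # of the union by default

    @property
    def union(self) -> int:
        return self.shared + self.only_a + self.only_b


def peptide_overlap(a: PeptideIndex, b: PeptideIndex,
                    denominator: str = "union") -> OverlapSummary:
    """Quantify peptide overlap between two databases digested identically.

    ``denominator='union'`` reports |a∩b| / |a∪b| (symmetric Venn reading);
    ``'target'`` reports |a∩b| / |a| instead.
    """
    if a.spec != b.spec:
        raise ValueError(f"digest specs differ: {a.spec} vs {b.spec}")
    shared = a.peptides & b.peptides
    union = a.peptides | b.peptides
    if denominator == "union":
        denom = len(union)
    elif denominator == "target":
        denom = len(a.peptides)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    pct = 100.0 * len(shared) / denom if denom else 0.0
    return OverlapSummary(
        shared=len(shared),
        only_a=len(a.peptides - b.peptides),
        only_b=len(b.peptides - a.peptides),
        shared_percent=pct,
    )


# ---------------------------------------------------------------------------
# Shuffled-target generation
# ---------------------------------------------------------------------------

def _record_rng(seed: int, accession: str) -> np.random.Generator:
    # per-record stream derived from the accession hash: reproducible
    # independent of record order in the database
    h = int.from_bytes(hashlib.sha256(accession.encode()).digest()[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, h]))


def shuffle_sequence(seq: str, rng: np.random.Generator,
                     fixed_residues: frozenset[str] = DEFAULT_FIXED_RESIDUES) -> str:
    """Permute the movable residues of one sequence, keeping every residue in
    ``fixed_residues`` at its original position."""
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    movable = ~np.isin(arr, [r.encode() for r in fixed_residues])
    idx = np.flatnonzero(movable)
    if idx.size > 1:
        out = arr.copy()
        out[idx] = arr[idx][rng.permutation(idx.size)]
        return out.tobytes().decode("ascii")
    return seq


def shuffle_database(db: ProteomeDB,
                     fixed_residues: Iterable[str] = DEFAULT_FIXED_RESIDUES,
                     seed: int = 0,
                     prefix: str = "SHUF_") -> ProteomeDB:
    """Produce a shuffled-target database.

    Each protein's residues are uniformly permuted except that every K, R and
    P (by default) stays at its original position, so the tryptic cleavage
    pattern — hence peptide length and mass distributions — is identical to
    the target's. Accessions gain the ``SHUF_`` prefix marking
    ``origin=shuffled``.
    """
    fixed = frozenset(fixed_residues)
    out: list[ProteinRecord] = []
    for rec in db:
        rng = _record_rng(seed, rec.accession)
        out.append(
            ProteinRecord(
                accession=prefix + rec.accession,
                sequence=shuffle_sequence(rec.sequence, rng, fixed),
                description=rec.description,
                origin=Origin.SHUFFLED,
            )
        )
    return ProteomeDB(out)


# ---------------------------------------------------------------------------
# FDR estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FdrEstimate:
    """Empirical FDR from an entrapment search: d decoy hits, t target hits,
    r the decoy/target database size ratio."""

    d: int
    t: int
    r: float
    fdr_hat: float

    @property
    def percent(self) -> float:
        return 100.0 * self.fdr_hat

    @classmethod
    def from_counts(cls, d: int, t: int, r: float) -> "FdrEstimate":
        if r <= 0:
            raise ValueError("r must be > 0")
        if d < 0 or t < 0 or t + d == 0:
            raise ValueError("need nonnegative counts with t + d > 0")
        return cls(d=d, t=t, r=r, fdr_hat=d * (1.0 + 1.0 / r) / (t + d))


HitSet = Mapping[str, "Origin | str"]

_DECOY_ORIGINS = {Origin.SHUFFLED, Origin.ENTRAPMENT}


def _classify(hits: HitSet) -> tuple[int, int]:
    d = t = 0
    bad: list[str] = []
    for acc, origin in hits.items():
        try:
            o = Origin(origin)
        except ValueError:
            bad.append(acc)
            continue
        if o in _DECOY_ORIGINS:
            d += 1
        else:
            t += 1
    if bad:
        raise ValueError(f"hits with unclassifiable origin: {bad[:10]}")
    return d, t


def estimate_fdr(hits: HitSet, r: float) -> FdrEstimate:
    """Estimate empirical FDR from a labeled protein hit set.

    ``hits`` maps accession -> origin (target / shuffled / entrapment); both
    shuffled and entrapment hits count as decoys.
    """
    d, t = _classify(hits)
    return FdrEstimate.from_counts(d=d, t=t, r=r)


@dataclass(frozen=True)
class AccumulatedFdr:
    """Per-replicate FDR versus the FDR of pooled (union) IDs."""

    per_replicate: tuple[FdrEstimate, ...]
    mean_fdr: float
    union: FdrEstimate


def accumulated_fdr(per_replicate_hits: Sequence[HitSet], r: float) -> AccumulatedFdr:
    """Contrast mean per-replicate FDR with the FDR of the union of hits.

    Target hits largely recur across technical replicates while false hits
    are scattered, so summing unique IDs over replicates (the "total IDs"
    summary) inflates the effective FDR relative to each replicate's.
    """
    if not per_replicate_hits:
        raise ValueError("need at least one replicate")
    estimates = tuple(estimate_fdr(h, r) for h in per_replicate_hits)
    union: dict[str, Origin] = {}
    for hits in per_replicate_hits:
        for acc, origin in hits.items():
            union[acc] = Origin(origin)
    return AccumulatedFdr(
        per_replicate=estimates,
        mean_fdr=float(np.mean([e.fdr_hat for e in estimates])),
        union=estimate_fdr(union, r),
    )


@dataclass(frozen=True)
class EntrapmentTruth:
    """Ground truth of a simulated entrapment search."""

    n_true: int
    n_false: int
    n_false_in_decoy: int
    true_fdr: float
    r: float


def simulate_entrapment_search(
    n_true: int,
    true_fdr: float,
    db_sizes: tuple[int, int],
    seed: int = 0,
    n_replicates: int = 1,
) -> tuple[list[dict[str, Origin]], EntrapmentTruth]:
    """Simulate labeled hit sets with a known false-hit fraction.

    ``db_sizes`` is (n_target_entries, n_decoy_entries). True hits are drawn
    once from the target space and shared across replicates; per replicate,
    false hits are drawn uniformly over the combined target+decoy space — a
    false hit lands in the decoy part with probability r/(1+r) — at a count
    making the expected false fraction equal ``true_fdr``.
    """
    if not 0.0 <= true_fdr < 1.0:
        raise ValueError("true_fdr must be in [0, 1)")
    n_target_db, n_decoy_db = db_sizes
    if n_target_db <= 0 or n_decoy_db <= 0:
        raise ValueError("database sizes must be positive")
    if n_true <= 0:
        raise ValueError("n_true must be positive")
    rng = np.random.default_rng(seed)
    r = n_decoy_db / n_target_db
    n_false = int(round(n_true * true_fdr / (1.0 - true_fdr)))
    p_decoy = n_decoy_db / (n_target_db + n_decoy_db)

    true_ids = rng.choice(n_target_db, size=min(n_true, n_target_db), replace=False)
    replicates: list[dict[str, Origin]] = []
    total_d = 0
    for _ in range(n_replicates):
        hits: dict[str, Origin] = {f"T{i:06d}": Origin.TARGET for i in true_ids}
        d_rep = int(rng.binomial(n_false, p_decoy)) if n_false else 0
        total_d += d_rep
        for i in rng.choice(n_decoy_db, size=min(d_rep, n_decoy_db), replace=False):
            hits[f"SHUF_D{i:06d}"] = Origin.SHUFFLED
        # false hits landing in the target database are indistinguishable
        # from true hits; draw them from target entries not already hit
        n_false_t = n_false - d_rep
        if n_false_t > 0:
            pool = np.setdiff1d(np.arange(n_target_db), true_ids, assume_unique=False)
            for i in rng.choice(pool, size=min(n_false_t, pool.size), replace=False):
                hits[f"T{i:06d}"] = Origin.TARGET
        replicates.append(hits)
    truth = EntrapmentTruth(
        n_true=n_true,
        n_false=n_false * n_replicates,
        n_false_in_decoy=total_d,
        true_fdr=true_fdr,
        r=r,
    )
    return replicates, truth
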