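"""Frequency-based population assignment with log-likelihood ratios.

The Paetkau-style assignment test scores an individual's multi-locus
genotype against each candidate breed by the product of Hardy–Weinberg
genotype probabilities at that breed's allele frequencies:

    log10 T(g | i) = sum_j log10 T(g_j | i)

with per-locus probability p^2, 2p(1-p) or (1-p)^2 for dosage 2, 1, 0.
The individual is assigned to the breed maximizing this log-likelihood;
the log-likelihood ratio (LLR) is the base-10 gap to the best alternative
breed, so a stringency level L demands a 10^L-fold likelihood advantage.

Frequencies estimated from finite reference samples can be 0 or 1, which
would make unseen alleles impossible (log-likelihood -inf); they are
smoothed into (0, 1) by clamping to [1/(2n+2), 1 - 1/(2n+2)] with n the
breed's genotyped sample count at the locus. When individuals are scored
against the reference panel they came from, leave-one-out frequencies
(the focal individual's own alleles removed from its breed's counts)
avoid self-assignment inflation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .popsim import PopulationFrequencies
from .feature_select import ImportanceRanking

__all__ = [
    "AssignmentResult",
    "estimate_frequencies",
    "smooth_frequencies",
    "genotype_loglik",
    "assign",
    "assign_matrix",
    "evaluate_success",
    "minimal_marker_counts",
]

DEFAULT_STRINGENCY_LEVELS = (1, 2, 3, 4)


@dataclass
class AssignmentResult:
    """Assignment outcome for one individual.

    ``llr`` is best-minus-second-best (>= 0 by construction); ``llr_true``
    is the diagnostic variant true-breed minus best other breed, negative
    when the individual is misassigned. ``passed[L]`` requires a correct
    assignment with ``llr`` strictly above L.
    """

    sample_id: str
    true_breed: str
    breeds: list[str]
    loglik: np.ndarray
    assigned_breed: str
    llr: float
    llr_true: float
    passed: dict[int, bool]
    runner_up: str
    tie: bool = False

    @property
    def correct(self) -> bool:
        return self.assigned_breed == self.true_breed


# ---------------------------------------------------------------------------
# frequency estimation


class _BreedCounts:
    """Per-breed counted-allele and called-genotype counts (for LOO math)."""

    def __init__(self, G: GenotypeMatrix):
        self.breeds = list(dict.fromkeys(G.breeds))
        labels = np.asarray(G.breeds)
        called = G.dosages != MISSING
        dos = np.where(called, G.dosages, 0)
        self.allele = np.empty((len(self.breeds), G.n_snps))
        self.called = np.empty((len(self.breeds), G.n_snps))
        self.n_samples = np.empty(len(self.breeds), dtype=int)
        for b, breed in enumerate(self.breeds):
            rows = labels == breed
            self.allele[b] = dos[rows].sum(axis=0)
            self.called[b] = called[rows].sum(axis=0)
            self.n_samples[b] = int(rows.sum())


def smooth_frequencies(freq: np.ndarray, n_samples: np.ndarray) -> np.ndarray:
    """Clamp frequencies into (0, 1): bound 1/(2n+2) per breed sample count.

    NaN cells (no called genotypes) are left NaN so the likelihood can skip
    them explicitly.
    """
    lo = 1.0 / (2.0 * np.asarray(n_samples, dtype=float) + 2.0)
    return np.clip(freq, lo[:, None], 1.0 - lo[:, None])


def estimate_frequencies(G: GenotypeMatrix, smooth: bool = True) -> PopulationFrequencies:
    """Per-breed counted-allele frequencies from a labeled reference panel.

    frequency = (sum of dosages) / (2 * n_called) per breed and SNP; cells
    with no called genotype are NaN (undefined, skipped by the likelihood).
    Breeds need >= 2 genotyped samples. Smoothing (default on) keeps every
    defined frequency strictly inside (0, 1).
    """
    counts = _BreedCounts(G)
    if np.any(counts.n_samples < 2):
        small = [b for b, n in zip(counts.breeds, counts.n_samples) if n < 2]
        raise ValueError(f"breeds with fewer than 2 samples: {', '.join(small)}")
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(counts.called > 0, counts.allele / (2.0 * counts.called), np.nan)
    if smooth:
        freq = smooth_frequencies(freq, counts.n_samples)
    return PopulationFrequencies(counts.breeds, list(G.snp_ids), freq)


# ---------------------------------------------------------------------------
# likelihoods


def _loglik_from_freq(dosage: np.ndarray, freq: np.ndarray) -> np.ndarray:
    """log10 HWE genotype likelihood per breed for one individual.

    ``dosage``: (n_snps,), ``freq``: (n_breeds, n_snps). Missing dosages
    and NaN frequencies are skipped.
    """
    usable = (dosage != MISSING) & np.isfinite(freq).all(axis=0)
    if not usable.any():
        raise ValueError("no usable locus: all genotypes missing or frequencies undefined")
    d = dosage[usable].astype(float)
    p = freq[:, usable]
    log_p, log_q = np.log10(p), np.log10(1.0 - p)
    # dosage 2: 2 log p; 1: log 2 + log p + log q; 0: 2 log q
    ll = (
        (d == 2) * 2.0 * log_p
        + (d == 1) * (np.log10(2.0) + log_p + log_q)
        + (d == 0) * 2.0 * log_q
    )
    return ll.sum(axis=1)


def genotype_loglik(
    sample: np.ndarray,
    freqs: PopulationFrequencies,
    snp_subset: Sequence[str] | None = None,
) -> np.ndarray:
    """log10 T(g|i) per breed for one dosage vector.

    ``snp_subset`` (ids) restricts the panel; by default every SNP in
    ``freqs`` is used. Missing genotypes and undefined frequency cells are
    skipped.
    """
    sample = np.asarray(sample)
    if sample.size != len(freqs.snp_ids):
        raise ValueError("dosage vector length does not match frequency panel")
    if snp_subset is not None:
        pos = {s: j for j, s in enumerate(freqs.snp_ids)}
        try:
            idx = np.array([pos[s] for s in snp_subset], dtype=int)
        except KeyError as e:
            raise KeyError(f"SNP {e.args[0]!r} not in frequency panel") from None
        return _loglik_from_freq(sample[idx], freqs.freq[:, idx])
    return _loglik_from_freq(sample, freqs.freq)


def assign(
    sample_id: str,
    true_breed: str,
    dosage: np.ndarray,
    freqs: PopulationFrequencies,
    snp_subset: Sequence[str] | None = None,
    stringency_levels: Sequence[int] = DEFAULT_STRINGENCY_LEVELS,
) -> AssignmentResult:
    """Assign one individual: argmax breed, LLR, and pass flags per level.

    Ties in the argmax are broken by breed order and flagged.
    """
    if len(freqs.breeds) < 2:
        raise ValueError("assignment requires at least 2 reference breeds")
    ll = genotype_loglik(dosage, freqs, snp_subset)
    order = np.argsort(-ll, kind="stable")
    best, second = order[0], order[1]
    tie = bool(ll[best] == ll[second])
    assigned = freqs.breeds[best]
    llr = float(ll[best] - ll[second])
    if true_breed in freqs.breeds:
        t = freqs.breed_index(true_breed)
        others = [i for i in range(len(freqs.breeds)) if i != t]
        llr_true = float(ll[t] - ll[others].max()) if others else float("nan")
    else:
        llr_true = float("nan")
    passed = {int(L): (assigned == true_breed) and (llr > L) for L in stringency_levels}
    return AssignmentResult(
        sample_id=sample_id,
        true_breed=true_breed,
        breeds=list(freqs.breeds),
        loglik=ll,
        assigned_breed=assigned,
        llr=llr,
        llr_true=llr_true,
        passed=passed,
        runner_up=freqs.breeds[second],
        tie=tie,
    )


def assign_matrix(
    G: GenotypeMatrix,
    reference: GenotypeMatrix | PopulationFrequencies,
    snp_subset: Sequence[str] | None = None,
    stringency_levels: Sequence[int] = DEFAULT_STRINGENCY_LEVELS,
    leave_one_out: bool = True,
) -> list[AssignmentResult]:
    """Assign every individual of ``G`` against a reference.

    When ``reference`` is a genotype panel, frequencies are estimated from
    it; if it is the *same* panel being scored and ``leave_one_out`` is on,
    each individual's own alleles are removed from its labeled breed's
    counts before computing that breed's frequencies (self-assignment
    without inflation). A precomputed :class:`PopulationFrequencies` is
    used as-is.
    """
    if isinstance(reference, PopulationFrequencies):
        freqs = reference
        return [
            assign(s, b, G.dosages[i], freqs, snp_subset, stringency_levels)
            for i, (s, b) in enumerate(zip(G.samples, G.breeds))
        ]
    counts = _BreedCounts(reference)
    if np.any(counts.n_samples < 2):
        raise ValueError("every reference breed needs >= 2 samples")
    self_panel = reference.samples == G.samples and reference.snp_ids == G.snp_ids
    base = estimate_frequencies(reference, smooth=True)
    results = []
    breed_row = {b: i for i, b in enumerate(counts.breeds)}
    for i, (s, b) in enumerate(zip(G.samples, G.breeds)):
        freqs = base
        if leave_one_out and self_panel and b in breed_row:
            r = breed_row[b]
            d = reference.dosages[i]
            called = d != MISSING
            allele = counts.allele[r] - np.where(called, d, 0)
            ncall = counts.called[r] - called
            with np.errstate(invalid="ignore", divide="ignore"):
                loo = np.where(ncall > 0, allele / (2.0 * ncall), np.nan)
            lo = 1.0 / (2.0 * max(counts.n_samples[r] - 1, 1) + 2.0)
            loo = np.clip(loo, lo, 1.0 - lo)
            freq = base.freq.copy()
            freq[r] = loo
            freqs = PopulationFrequencies(list(base.breeds), list(base.snp_ids), freq)
        results.append(assign(s, b, G.dosages[i], freqs, snp_subset, stringency_levels))
    return results


def results_to_frame(results: list[AssignmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id,
            "true_breed": r.true_breed,
            "assigned_breed": r.assigned_breed,
            "runner_up": r.runner_up,
            "llr": r.llr,
            "llr_true": r.llr_true,
            "correct": int(r.correct),
            "tie": int(r.tie),
        }
        for L, ok in sorted(r.passed.items()):
            row[f"pass_llr_gt_{L}"] = int(ok)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# success curves


def evaluate_success(
    G: GenotypeMatrix,
    ranking: ImportanceRanking,
    marker_counts: Sequence[int],
    stringency_levels: Sequence[int] = DEFAULT_STRINGENCY_LEVELS,
    leave_one_out: bool = True,
) -> pd.DataFrame:
    """Self-assignment success across nested top-k marker panels.

    For each k in ``marker_counts`` (ascending), every individual is
    assigned with the ranking's top-k SNPs (leave-one-out frequencies by
    default) and the count and percentage passing each stringency level is
    tabulated. Columns: method, k, level, n_pass, pct_pass, n_total.
    """
    marker_counts = list(marker_counts)
    if marker_counts != sorted(marker_counts):
        raise ValueError("marker_counts must be sorted ascending")
    if marker_counts and marker_counts[-1] > len(ranking.snp_ids):
        raise ValueError(
            f"marker count {marker_counts[-1]} exceeds panel size {len(ranking.snp_ids)}"
        )
    rows = []
    n_total = G.n_samples
    for k in marker_counts:
        subset = ranking.top(k)
        results = assign_matrix(
            G, G, snp_subset=subset, stringency_levels=stringency_levels,
            leave_one_out=leave_one_out,
        )
        for L in stringency_levels:
            n_pass = sum(r.passed[int(L)] for r in results)
            rows.append(
                {
                    "method": ranking.method,
                    "k": k,
                    "level": int(L),
                    "n_pass": n_pass,
                    "pct_pass": 100.0 * n_pass / n_total,
                    "n_total": n_total,
                }
            )
    return pd.DataFrame(rows)


def minimal_marker_counts(
    success: pd.DataFrame,
    target_rates: Sequence[float] = (70.0, 90.0, 95.0, 98.0),
) -> pd.DataFrame:
    """Smallest evaluated k reaching each target success rate per level.

    ``k`` is NaN ("not reached") when no evaluated marker count attains the
    rate. Operates on the grid actually evaluated, not by interpolation.
    """
    rows = []
    for (method, level), grp in success.groupby(["method", "level"], sort=True):
        grp = grp.sort_values("k")
        for rate in target_rates:
            hit = grp[grp["pct_pass"] >= rate]
            rows.append(
                {
                    "method": method,
                    "level": int(level),
                    "target_pct": float(rate),
                    "min_k": int(hit["k"].iloc[0]) if len(hit) else np.nan,
                }
            )
    return pd.DataFrame(rows)
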