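"""Multi-breed genotype simulation under the Balding–Nichols model.

Breed allele frequencies diverge from a shared ancestral frequency ``p``
according to ``Beta(p (1-F)/F, (1-p)(1-F)/F)``, whose mean is ``p`` and
variance ``p (1-p) F`` — the standard Balding–Nichols parameterization in
which ``F`` plays the role of FST. A configurable minority of SNPs is
"planted" with a much larger ``F`` than the neutral background, emulating a
dense chip on which only some markers are strongly breed-discriminant.
Genotypes are binomial draws from the breed frequency (Hardy–Weinberg
within breed, no linkage); F1 hybrids draw one allele from each parent
breed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "PopulationFrequencies",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_hybrids",
    "intersect_panels",
    "fst_estimate",
]

# Beta draws collapse to the ancestral frequency below this divergence.
_F_EPS = 1e-12


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of one simulated multi-breed panel.

    Defaults emulate a many-breed chip study at desk scale: 5 breeds of 30
    individuals, 2,000 SNPs of which 100 are strongly discriminant
    (F = 0.35) against a weakly structured background (F = 0.02), with
    0.2% missing genotypes.
    """

    n_breeds: int = 5
    n_per_breed: int = 30
    n_snps: int = 2000
    n_discriminant: int = 100
    fst_neutral: float = 0.02
    fst_discriminant: float = 0.35
    missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breeds < 2:
            raise ValueError("need at least 2 breeds")
        if min(self.n_per_breed, self.n_snps) < 1:
            raise ValueError("n_per_breed and n_snps must be positive")
        if not 0 <= self.n_discriminant <= self.n_snps:
            raise ValueError("n_discriminant must lie in [0, n_snps]")
        for name in ("fst_neutral", "fst_discriminant"):
            f = getattr(self, name)
            if not 0 <= f < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {f}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class PopulationFrequencies:
    """Per-breed, per-SNP counted-allele frequencies.

    ``freq[b, j]`` is the frequency in breed ``breeds[b]`` of the allele
    whose copies the dosage counts at SNP ``snp_ids[j]``.
    """

    breeds: list[str]
    snp_ids: list[str]
    freq: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.breeds), len(self.snp_ids)):
            raise ValueError(
                f"frequency matrix {self.freq.shape} does not match "
                f"{len(self.breeds)} breeds x {len(self.snp_ids)} SNPs"
            )
        finite = np.isfinite(self.freq)
        if np.any((self.freq[finite] < 0) | (self.freq[finite] > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")

    def breed_index(self, breed: str) -> int:
        try:
            return self.breeds.index(breed)
        except ValueError:
            raise KeyError(f"unknown breed {breed!r}") from None


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators so each stage's stream is stable."""
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _bn_draw(rng: np.random.Generator, p: np.ndarray, F: float, size: tuple) -> np.ndarray:
    """Balding–Nichols Beta draw with mean ``p`` and variance ``p(1-p)F``."""
    if F < _F_EPS:
        return np.broadcast_to(p, size).copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(np.broadcast_to(a, size), np.broadcast_to(b, size))


def simulate_frequencies(cfg: SimulationConfig) -> tuple[PopulationFrequencies, list[str]]:
    """Draw per-breed allele frequencies; returns (frequencies, planted ids).

    Ancestral frequencies are uniform on [0.05, 0.95]; planted discriminant
    SNPs (a random subset of ``n_discriminant``) diverge with
    ``fst_discriminant``, the rest with ``fst_neutral``. Deterministic given
    ``cfg.seed``.
    """
    rng_anc, rng_plant, rng_beta = _rngs(cfg.seed, 3)
    p_anc = rng_anc.uniform(0.05, 0.95, size=cfg.n_snps)
    planted_idx = np.sort(rng_plant.choice(cfg.n_snps, size=cfg.n_discriminant, replace=False))
    F = np.full(cfg.n_snps, cfg.fst_neutral)
    F[planted_idx] = cfg.fst_discriminant
    freq = np.empty((cfg.n_breeds, cfg.n_snps))
    for fval in np.unique(F):
        cols = F == fval
        freq[:, cols] = _bn_draw(rng_beta, p_anc[cols], float(fval), (cfg.n_breeds, int(cols.sum())))
    width = len(str(cfg.n_snps))
    snp_ids = [f"snp{j + 1:0{width}d}" for j in range(cfg.n_snps)]
    breeds = [f"breed{b + 1}" for b in range(cfg.n_breeds)]
    planted = [snp_ids[j] for j in planted_idx]
    return PopulationFrequencies(breeds, snp_ids, freq), planted


def simulate_genotypes(freqs: PopulationFrequencies, cfg: SimulationConfig) -> GenotypeMatrix:
    """Binomial(2, breed frequency) dosages with missingness injected.

    Sample ids are ``<breed>_<k>``; deterministic given ``cfg.seed``.
    """
    rng_geno, rng_miss = _rngs(cfg.seed + 1, 2)
    n_total = len(freqs.breeds) * cfg.n_per_breed
    dosages = np.empty((n_total, len(freqs.snp_ids)), dtype=np.int16)
    samples: list[str] = []
    breeds: list[str] = []
    row = 0
    for b, breed in enumerate(freqs.breeds):
        block = rng_geno.binomial(2, freqs.freq[b], size=(cfg.n_per_breed, len(freqs.snp_ids)))
        dosages[row : row + cfg.n_per_breed] = block
        samples.extend(f"{breed}_{k + 1}" for k in range(cfg.n_per_breed))
        breeds.extend([breed] * cfg.n_per_breed)
        row += cfg.n_per_breed
    if cfg.missing_rate > 0:
        mask = rng_miss.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING
    return GenotypeMatrix(samples, breeds, list(freqs.snp_ids), dosages)


def simulate_hybrids(
    freqs: PopulationFrequencies,
    breed_a: str,
    breed_b: str,
    n: int,
    seed: int,
    label: str | None = None,
) -> GenotypeMatrix:
    """F1 hybrids: one allele drawn from each parent breed's frequencies.

    Hybrids carry a distinct breed tag (default ``hybrid(<a>x<b>)``) so they
    are never mistaken for reference individuals downstream.
    """
    if breed_a == breed_b:
        raise ValueError("hybrid parents must be two distinct breeds")
    ia, ib = freqs.breed_index(breed_a), freqs.breed_index(breed_b)
    rng = np.random.default_rng(seed)
    pa, pb = freqs.freq[ia], freqs.freq[ib]
    dosages = (
        rng.binomial(1, pa, size=(n, len(freqs.snp_ids)))
        + rng.binomial(1, pb, size=(n, len(freqs.snp_ids)))
    ).astype(np.int16)
    tag = label or f"hybrid({breed_a}x{breed_b})"
    samples = [f"{tag}_{k + 1}" for k in range(n)]
    return GenotypeMatrix(samples, [tag] * n, list(freqs.snp_ids), dosages)


def intersect_panels(G_a: GenotypeMatrix, G_b: GenotypeMatrix) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two matrices to their shared SNP ids, in ``G_a``'s order."""
    shared = set(G_a.snp_ids) & set(G_b.snp_ids)
    if not shared:
        raise ValueError("panels share no SNP ids")
    common = [s for s in G_a.snp_ids if s in shared]
    return G_a.select_snp_ids(common), G_b.select_snp_ids(common)


def fst_estimate(freqs: PopulationFrequencies) -> np.ndarray:
    """Per-SNP divergence var(p_breed) / (p_bar (1 - p_bar)).

    A frequency-level analogue of FST used to check that planted SNPs are
    more diverged than neutral ones; not a sample-based estimator.
    """
    pbar = freqs.freq.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return freqs.freq.var(axis=0) / (pbar * (1.0 - pbar))


def write_snp_list(snp_ids: list[str], path: str | Path) -> None:
    """One-column text file of SNP ids (e.g. the planted discriminant set)."""
    Path(path).write_text("".join(s + "\n" for s in snp_ids))


def read_snp_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
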