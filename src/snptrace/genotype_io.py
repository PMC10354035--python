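"""Dosage-coded genotype matrices: I/O, validation, QC and per-SNP summaries.

Genotypes are stored as allele *dosages*: the number of copies of the
counted allele carried by a diploid individual, so 0 (AA), 1 (AB) or 2 (BB).
For VCF input the counted allele is the ALT allele (0/0 -> 0, 0/1 -> 1,
1/1 -> 2); for the tab-separated dosage dialect the coding is whatever the
producer used, as long as it is consistent across panels. Missing genotypes
are held as the sentinel :data:`MISSING` and written as ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SnpSummary",
    "GenotypeParseError",
    "EmptyPanelError",
    "read_genotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_sample_map",
    "filter_call_rate",
    "filter_sample_call_rate",
    "summarize_snps",
]

#: Sentinel dosage for a missing genotype. Distinct from {0, 1, 2}.
MISSING: int = -1


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed under the declared format."""


class EmptyPanelError(ValueError):
    """A filtering step removed every SNP (or every sample)."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with breed labels.

    Parameters
    ----------
    samples
        Ordered unique sample identifiers (matrix rows).
    breeds
        Breed label per sample, aligned with ``samples``.
    snp_ids
        Ordered unique SNP identifiers (matrix columns).
    dosages
        ``(n_samples, n_snps)`` integer array with entries in ``{0, 1, 2}``
        or :data:`MISSING`.
    """

    samples: list[str]
    breeds: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        n, p = self.dosages.shape
        if len(self.samples) != n or len(self.breeds) != n:
            raise ValueError(
                f"sample/breed labels ({len(self.samples)}/{len(self.breeds)}) "
                f"do not match {n} matrix rows"
            )
        if len(self.snp_ids) != p:
            raise ValueError(
                f"{len(self.snp_ids)} SNP ids do not match {p} matrix columns"
            )
        if len(set(self.samples)) != n:
            raise ValueError("sample IDs are not unique")
        if len(set(self.snp_ids)) != p:
            raise ValueError("SNP IDs are not unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosages[i, j]} at sample "
                f"{self.samples[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def call_rates(self) -> np.ndarray:
        """Per-SNP fraction of non-missing genotypes."""
        return 1.0 - self.missing_mask().mean(axis=0)

    # -- subsetting --------------------------------------------------------

    def take_snps(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            breeds=list(self.breeds),
            snp_ids=[self.snp_ids[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            breeds=[self.breeds[i] for i in idx],
            snp_ids=list(self.snp_ids),
            dosages=self.dosages[idx, :].copy(),
        )

    def select_snp_ids(self, ids: Iterable[str]) -> "GenotypeMatrix":
        """Restrict to the given SNP ids, in the order given."""
        pos = {s: j for j, s in enumerate(self.snp_ids)}
        try:
            idx = [pos[s] for s in ids]
        except KeyError as e:
            raise KeyError(f"SNP id {e.args[0]!r} not in panel") from None
        return self.take_snps(idx)

    def concat_samples(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.snp_ids != other.snp_ids:
            raise ValueError("cannot stack matrices with different SNP panels")
        return GenotypeMatrix(
            samples=self.samples + other.samples,
            breeds=self.breeds + other.breeds,
            snp_ids=list(self.snp_ids),
            dosages=np.vstack([self.dosages, other.dosages]),
        )


@dataclass
class SnpSummary:
    """Descriptive statistics for one SNP (optionally within one breed).

    ``maf``/``het_obs`` are ``nan`` when no genotype was called — the
    undefined state is explicit, never silently zero.
    """

    snp_id: str
    call_rate: float
    maf: float
    het_obs: float
    breed: str | None = None


# ---------------------------------------------------------------------------
# reading / writing


def read_genotypes(path: str | Path, format: str, sample_map: str | Path | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from ``path``.

    ``format`` is ``"vcf"`` or ``"dosage_tsv"``. VCF requires a companion
    ``sample_map`` TSV (columns: sample_id, breed) supplying breed labels.
    """
    if format == "vcf":
        if sample_map is None:
            raise ValueError("VCF input requires a sample_map TSV (sample_id\tbreed)")
        return read_vcf(path, sample_map)
    if format == "dosage_tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}; expected 'vcf' or 'dosage_tsv'")


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id -> breed TSV (no header)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenotypeParseError(f"{path}: line {ln}: expected 'sample_id<TAB>breed'")
            mapping[parts[0]] = parts[1]
    return mapping


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the dosage TSV dialect.

    Header row: ``sample_id  breed  <snp_id_1> ... <snp_id_p>``; one row per
    individual; missing genotypes written ``NA``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "breed":
            raise GenotypeParseError(
                f"{path}: line 1: header must start with 'sample_id<TAB>breed'"
            )
        snp_ids = header[2:]
        samples: list[str] = []
        breeds: list[str] = []
        rows: list[list[int]] = []
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise GenotypeParseError(
                    f"{path}: line {ln}: expected {len(header)} fields, got {len(parts)}"
                )
            samples.append(parts[0])
            breeds.append(parts[1])
            row = []
            for j, tok in enumerate(parts[2:]):
                if tok == "NA":
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise GenotypeParseError(
                        f"{path}: line {ln}: invalid dosage {tok!r} for SNP {snp_ids[j]!r}"
                    )
            rows.append(row)
    if not rows:
        raise GenotypeParseError(f"{path}: no sample rows")
    return GenotypeMatrix(samples, breeds, snp_ids, np.array(rows, dtype=np.int16))


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Write ``G`` in the dosage TSV dialect (missing as ``NA``)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tbreed\t" + "\t".join(G.snp_ids) + "\n")
        for i, (s, b) in enumerate(zip(G.samples, G.breeds)):
            toks = ["NA" if d == MISSING else str(int(d)) for d in G.dosages[i]]
            fh.write(s + "\t" + b + "\t" + "\t".join(toks) + "\n")


def read_vcf(path: str | Path, sample_map: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF (v4.x) into dosages.

    GT fields are collapsed to counted-allele (ALT) dosage: 0/0 -> 0,
    0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing. Half-calls (e.g. ./1) are
    treated as missing. Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    path = Path(path)
    breed_of = read_sample_map(sample_map)
    try:
        vcf = VCF(str(path))
    except Exception as e:  # cyvcf2 raises bare exceptions on bad files
        raise GenotypeParseError(f"{path}: not a readable VCF: {e}") from e
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in breed_of]
    if missing_samples:
        raise GenotypeParseError(
            f"{path}: samples absent from sample map: {', '.join(missing_samples)}"
        )
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: multi-allelic site {var.ID or f'{var.CHROM}:{var.POS}'} "
                f"(ALT={','.join(var.ALT)}) is not supported"
            )
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        col = np.full(len(samples), MISSING, dtype=np.int16)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a in (0, 1) and b in (0, 1):  # half-calls stay missing
                col[i] = a + b
        cols.append(col)
    vcf.close()
    if not cols:
        raise GenotypeParseError(f"{path}: VCF contains no variant records")
    dosages = np.column_stack(cols)
    return GenotypeMatrix(samples, [breed_of[s] for s in samples], snp_ids, dosages)


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write ``G`` as a minimal VCFv4.2 with synthetic positions and alleles.

    Dosages become GT fields on chromosome 1 at consecutive positions with
    placeholder REF/ALT (A/G); intended for interchange of simulated data,
    not for variants with real coordinates.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.samples) + "\n")
        for j, sid in enumerate(G.snp_ids):
            gts = "\t".join(_VCF_GT[int(d)] for d in G.dosages[:, j])
            fh.write(f"1\t{j + 1}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# QC


def filter_call_rate(G: GenotypeMatrix, min_call_rate: float) -> GenotypeMatrix:
    """Drop SNPs whose call rate is below ``min_call_rate`` (keep ``>=``).

    Sample set and surviving column order are unchanged.
    """
    if not 0 < min_call_rate <= 1:
        raise ValueError(f"min_call_rate must be in (0, 1], got {min_call_rate}")
    keep = np.flatnonzero(G.call_rates() >= min_call_rate)
    if keep.size == 0:
        raise EmptyPanelError(
            f"call-rate filter at {min_call_rate} removed all {G.n_snps} SNPs"
        )
    return G.take_snps(keep)


def filter_sample_call_rate(G: GenotypeMatrix, min_call_rate: float) -> GenotypeMatrix:
    """Optional per-sample analogue of :func:`filter_call_rate`."""
    if not 0 < min_call_rate <= 1:
        raise ValueError(f"min_call_rate must be in (0, 1], got {min_call_rate}")
    rates = 1.0 - G.missing_mask().mean(axis=1)
    keep = np.flatnonzero(rates >= min_call_rate)
    if keep.size == 0:
        raise EmptyPanelError(
            f"sample call-rate filter at {min_call_rate} removed all samples"
        )
    return G.take_samples(keep)


# ---------------------------------------------------------------------------
# summaries


def _summarize_block(dos: np.ndarray, snp_ids: Sequence[str], breed: str | None) -> list[SnpSummary]:
    called = dos != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / dos.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dos, 0).sum(axis=0) / (2.0 * n_called)
        maf = np.minimum(p, 1.0 - p)
        het = np.where(called, dos == 1, False).sum(axis=0) / n_called
    out = []
    for j, sid in enumerate(snp_ids):
        if n_called[j] == 0:
            out.append(SnpSummary(sid, 0.0, math.nan, math.nan, breed))
        else:
            out.append(SnpSummary(sid, float(call_rate[j]), float(maf[j]), float(het[j]), breed))
    return out


def summarize_snps(G: GenotypeMatrix, by_breed: bool = False) -> list[SnpSummary]:
    """Per-SNP call rate, minor-allele frequency and observed heterozygosity.

    MAF is ``min(p, 1-p)`` with ``p = sum(dosages) / (2 * n_called)``;
    het_obs is the fraction of called genotypes equal to 1. With
    ``by_breed`` the statistics are computed within each breed.
    """
    if G.n_samples == 0 or G.n_snps == 0:
        raise ValueError("cannot summarize an empty genotype matrix")
    if not by_breed:
        return _summarize_block(G.dosages, G.snp_ids, None)
    out: list[SnpSummary] = []
    breeds = np.asarray(G.breeds)
    for b in dict.fromkeys(G.breeds):  # preserves first-appearance order
        rows = np.flatnonzero(breeds == b)
        out.extend(_summarize_block(G.dosages[rows, :], G.snp_ids, b))
    return out


def summaries_to_frame(summaries: list[SnpSummary]) -> pd.DataFrame:
    """Tabulate :class:`SnpSummary` records as a DataFrame."""
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in summaries],
            "breed": [s.breed for s in summaries],
            "call_rate": [s.call_rate for s in summaries],
            "maf": [s.maf for s in summaries],
            "het_obs": [s.het_obs for s in summaries],
        }
    )
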