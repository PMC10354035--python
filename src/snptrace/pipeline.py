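"""End-to-end orchestration: simulate/load -> QC -> select -> assign -> structure.

The pipeline mirrors the full marker-reduction workflow: obtain a labeled
dosage panel (from files or the built-in simulator), quality-filter it,
build importance rankings with each configured method, compare the
rankings, trace self-assignment success across nested top-k panels, and
emit PCA scores, allele-sharing distances and a Neighbor-Joining tree.
Every output is a text table; a manifest records file hashes, seeds and
versions so any stage can be re-run and checked for identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import (
    GenotypeMatrix,
    filter_call_rate,
    read_genotypes,
    summaries_to_frame,
    summarize_snps,
    write_dosage_tsv,
)
from .popsim import (
    PopulationFrequencies,
    SimulationConfig,
    intersect_panels,
    simulate_frequencies,
    simulate_genotypes,
    write_snp_list,
)
from .neuralnet import TrainingConfig
from .feature_select import ImportanceRanking, compare_rankings, select_snps
from .assignment import (
    assign_matrix,
    estimate_frequencies,
    evaluate_success,
    minimal_marker_counts,
    results_to_frame,
)
from .popstructure import allele_sharing_distance, neighbor_joining, pca_scores

__all__ = ["PipelineConfig", "run_pipeline", "validate_on_holdout"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; parsable from a flat key=value text file.

    When ``input_genotypes`` is unset the built-in simulator supplies the
    panel (``n_breeds`` .. ``missing_rate`` keys). ``marker_counts`` and
    ``top_n`` are clipped to the post-QC panel size at run time.
    """

    # input
    input_genotypes: str | None = None
    input_format: str = "dosage_tsv"
    sample_map: str | None = None
    # simulation (used when input_genotypes is None)
    n_breeds: int = 5
    n_per_breed: int = 30
    n_snps: int = 2000
    n_discriminant: int = 100
    fst_neutral: float = 0.02
    fst_discriminant: float = 0.35
    missing_rate: float = 0.002
    # QC
    min_call_rate: float = 0.99
    # selection
    methods: tuple[str, ...] = ("dnn", "garson", "olden")
    chunk_size: int = 1000
    n_iterations: int = 1
    hidden_dnn: tuple[int, ...] = (40, 38)
    hidden_single: tuple[int, ...] = (40,)
    learning_rate: float = 1.0
    max_epochs: int = 600
    top_n: int = 460
    top_k: int = 460
    # assignment
    marker_counts: tuple[int, ...] = (50, 75, 100, 125, 150, 200, 250, 300, 350)
    stringency_levels: tuple[int, ...] = (1, 2, 3, 4)
    target_rates: tuple[float, ...] = (70.0, 90.0, 95.0, 98.0)
    leave_one_out: bool = True
    # structure
    pca_components: int = 2
    # bookkeeping
    out_dir: str = "snptrace_out"
    seed: int = 0

    def validate(self) -> None:
        if self.input_genotypes is not None and not Path(self.input_genotypes).exists():
            raise FileNotFoundError(f"input_genotypes not found: {self.input_genotypes}")
        if self.input_format == "vcf" and self.input_genotypes is not None:
            if self.sample_map is None or not Path(self.sample_map).exists():
                raise FileNotFoundError("VCF input requires an existing sample_map")
        if not self.methods:
            raise ValueError("no selection methods configured")
        if not self.marker_counts:
            raise ValueError("marker_counts grid is empty")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text file ('#' starts a comment)."""
        raw: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: line {ln}: expected 'key = value'")
                k, v = (t.strip() for t in line.split("=", 1))
                raw[k] = v
        kwargs = {}
        types = {f.name: f for f in dc_fields(cls)}
        for k, v in raw.items():
            if k not in types:
                raise ValueError(f"{path}: unknown config key {k!r}")
            kwargs[k] = _coerce(k, v)
        return cls(**kwargs)


_TUPLE_INT = {"methods", "hidden_dnn", "hidden_single", "marker_counts", "stringency_levels"}


def _coerce(key: str, value: str):
    if key == "methods":
        return tuple(t.strip() for t in value.split(",") if t.strip())
    if key in ("hidden_dnn", "hidden_single", "marker_counts", "stringency_levels"):
        return tuple(int(t) for t in value.split(",") if t.strip())
    if key == "target_rates":
        return tuple(float(t) for t in value.split(",") if t.strip())
    if key in ("input_genotypes", "sample_map", "input_format", "out_dir"):
        return None if value.lower() == "none" else value
    if key == "leave_one_out":
        return value.lower() in ("1", "true", "yes", "on")
    if key in ("min_call_rate", "fst_neutral", "fst_discriminant", "missing_rate", "learning_rate"):
        return float(value)
    return int(value)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest (also written to disk).

    Re-running with an identical config and seed reproduces byte-identical
    text outputs. A stage failure aborts with the stage named; outputs of
    completed stages are left in place.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "snptrace_version": __version__,
        "seed": cfg.seed,
        "config": {f.name: getattr(cfg, f.name) for f in dc_fields(cfg)},
        "stages": {},
    }
    produced: list[Path] = []
    stage = "input"
    try:
        t0 = time.perf_counter()
        if cfg.input_genotypes is None:
            sim = SimulationConfig(
                n_breeds=cfg.n_breeds,
                n_per_breed=cfg.n_per_breed,
                n_snps=cfg.n_snps,
                n_discriminant=cfg.n_discriminant,
                fst_neutral=cfg.fst_neutral,
                fst_discriminant=cfg.fst_discriminant,
                missing_rate=cfg.missing_rate,
                seed=cfg.seed,
            )
            freqs, planted = simulate_frequencies(sim)
            G = simulate_genotypes(freqs, sim)
            write_dosage_tsv(G, out / "genotypes.tsv")
            write_snp_list(planted, out / "planted_snps.txt")
            produced += [out / "genotypes.tsv", out / "planted_snps.txt"]
        else:
            G = read_genotypes(cfg.input_genotypes, cfg.input_format, cfg.sample_map)
        _stage_done(manifest, stage, produced, t0)

        stage = "qc"
        t0 = time.perf_counter()
        G = filter_call_rate(G, cfg.min_call_rate)
        write_dosage_tsv(G, out / "qc_genotypes.tsv")
        _write_tsv(summaries_to_frame(summarize_snps(G)), out / "snp_summaries.tsv")
        produced = [out / "qc_genotypes.tsv", out / "snp_summaries.tsv"]
        _stage_done(manifest, stage, produced, t0)
        logger.info("QC panel: %d samples x %d SNPs", G.n_samples, G.n_snps)

        stage = "select"
        t0 = time.perf_counter()
        rankings: list[ImportanceRanking] = []
        produced = []
        top_k = min(cfg.top_k, G.n_snps)
        for method in cfg.methods:
            tc = TrainingConfig(
                hidden_layers=cfg.hidden_dnn if method == "dnn" else cfg.hidden_single,
                output_mode="one_hot" if method == "dnn" else "scaled_class_index",
                learning_rate=cfg.learning_rate,
                max_epochs=cfg.max_epochs,
                seed=cfg.seed,
            )
            rk = select_snps(
                G, method, tc, chunk_size=cfg.chunk_size,
                n_iterations=cfg.n_iterations, top_k=top_k,
            )
            rk.to_tsv(out / f"ranking_{method}.tsv")
            produced.append(out / f"ranking_{method}.tsv")
            rankings.append(rk)
            logger.info("%s: %d SNPs selected", method, len(rk.selected))
        _stage_done(manifest, stage, produced, t0)

        stage = "compare"
        t0 = time.perf_counter()
        produced = []
        if len(rankings) >= 2:
            cmp_df = compare_rankings(rankings, top_n=min(cfg.top_n, G.n_snps))
            _write_tsv(cmp_df, out / "ranking_comparison.tsv")
            produced = [out / "ranking_comparison.tsv"]
        _stage_done(manifest, stage, produced, t0)

        stage = "assign"
        t0 = time.perf_counter()
        produced = []
        counts = tuple(k for k in cfg.marker_counts if k <= G.n_snps) or (G.n_snps,)
        success_frames, assign_frames = [], []
        for rk in rankings:
            success_frames.append(
                evaluate_success(
                    G, rk, counts, cfg.stringency_levels, leave_one_out=cfg.leave_one_out
                )
            )
            res = assign_matrix(
                G, G, snp_subset=rk.top(min(cfg.top_n, G.n_snps)),
                stringency_levels=cfg.stringency_levels, leave_one_out=cfg.leave_one_out,
            )
            df = results_to_frame(res)
            df.insert(0, "method", rk.method)
            assign_frames.append(df)
        success = pd.concat(success_frames, ignore_index=True)
        _write_tsv(success, out / "success_curves.tsv")
        _write_tsv(minimal_marker_counts(success, cfg.target_rates), out / "minimal_markers.tsv")
        _write_tsv(pd.concat(assign_frames, ignore_index=True), out / "assignments.tsv")
        produced = [out / "success_curves.tsv", out / "minimal_markers.tsv", out / "assignments.tsv"]
        _stage_done(manifest, stage, produced, t0)

        stage = "structure"
        t0 = time.perf_counter()
        pca = pca_scores(G, n_components=min(cfg.pca_components, G.n_samples - 1, G.n_snps))
        pca.to_tsv(out / "pca_scores.tsv")
        dmat = allele_sharing_distance(G)
        dmat.to_phylip(out / "distances.phy")
        (out / "njtree.nwk").write_text(neighbor_joining(dmat) + "\n")
        produced = [out / "pca_scores.tsv", out / "distances.phy", out / "njtree.nwk"]
        _stage_done(manifest, stage, produced, t0)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _stage_done(manifest: dict, stage: str, files: list[Path], t0: float) -> None:
    manifest["stages"][stage] = {
        "outputs": {f.name: _sha256(f) for f in files},
    }
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# holdout validation


def validate_on_holdout(
    train: GenotypeMatrix,
    holdout: GenotypeMatrix,
    ranking: ImportanceRanking,
    breed_map: dict[str, str] | None = None,
    top_n: int = 460,
    stringency_levels: Sequence[int] = (1, 2, 3, 4),
) -> dict:
    """Carry a training-panel ranking onto an independent holdout panel.

    The two panels are intersected on shared SNP ids; the report counts how
    many selected and top-``top_n`` SNPs survive, then assigns every
    holdout individual against training-panel frequencies restricted to
    the surviving ranked SNPs, and builds a Neighbor-Joining tree of the
    holdout individuals. ``breed_map`` translates holdout breed labels to
    training labels (identity by default); unmapped labels are an error.
    """
    train_breeds = set(train.breeds)
    bmap = breed_map or {}
    unmapped = [b for b in set(holdout.breeds) if bmap.get(b, b) not in train_breeds]
    if unmapped:
        raise ValueError(
            f"holdout breeds not mapped onto training breeds: {', '.join(sorted(unmapped))}"
        )
    tr, ho = intersect_panels(train, holdout)
    shared = set(tr.snp_ids)
    surviving_selected = [s for s in ranking.selected if s in shared]
    top = ranking.top(min(top_n, len(ranking.snp_ids)))
    surviving_top = [s for s in top if s in shared]
    ranked_shared = [s for s in ranking.top(len(ranking.snp_ids)) if s in shared]
    if not ranked_shared:
        raise ValueError("no ranked SNP survives the panel intersection")
    usable = surviving_selected or ranked_shared
    freqs = estimate_frequencies(tr, smooth=True)
    mapped = GenotypeMatrix(
        samples=list(ho.samples),
        breeds=[bmap.get(b, b) for b in ho.breeds],
        snp_ids=list(ho.snp_ids),
        dosages=ho.dosages.copy(),
    )
    results = assign_matrix(
        mapped, freqs, snp_subset=usable, stringency_levels=stringency_levels
    )
    dmat = allele_sharing_distance(ho, snp_subset=usable if len(usable) >= 1 else None)
    tree = neighbor_joining(dmat)
    n_correct = sum(r.correct for r in results)
    return {
        "n_shared_snps": len(shared),
        "n_selected": len(ranking.selected),
        "n_selected_surviving": len(surviving_selected),
        "n_top_surviving": len(surviving_top),
        "top_n": min(top_n, len(ranking.snp_ids)),
        "n_holdout": mapped.n_samples,
        "n_correct": n_correct,
        "pct_correct": 100.0 * n_correct / mapped.n_samples,
        "assignments": results_to_frame(results),
        "njtree": tree,
    }
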