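"""Per-SNP importance from fitted network weights, thresholding and ranking.

Three importance readouts are implemented:

* ``dnn`` — the first-hidden-layer weight criterion: the score of input
  *j* is ``max_h |W_jh|`` over the first weight matrix only. The deeper
  layers are deliberately ignored: every downstream connection is a
  function of the first layer's load, so the first-layer magnitudes carry
  the variable-level signal. Selection keeps input *j* when its score
  strictly exceeds the threshold ``mean(|W|) + sd(|W|)`` pooled over all
  first-layer weight magnitudes of the same network.
* ``garson`` — Garson/Goh weight partitioning for single-hidden-layer
  networks; non-negative relative importances that sum to one.
* ``olden`` — Olden & Jackson connection weights: the signed sum over
  hidden units of input-hidden times hidden-output weights.

Genome-wide rankings are built chunk-wise: the panel is partitioned into
column blocks, one network is trained per block, and the per-block scores
are concatenated. Thresholds (dnn) are applied within each block's
network, since raw weight magnitudes are only comparable inside one fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .genotype_io import GenotypeMatrix
from .neuralnet import NetworkWeights, TrainingConfig, partition_snps, train_network

__all__ = [
    "ImportanceRanking",
    "dnn_importance",
    "selection_threshold",
    "garson_importance",
    "olden_importance",
    "select_snps",
    "compare_rankings",
]

METHODS = ("dnn", "garson", "olden")


@dataclass
class ImportanceRanking:
    """Per-SNP importance scores and dense ranks for one method.

    Ranks are dense (1 = most important), by decreasing ``|score|`` for
    olden and decreasing score otherwise; ties within a rank are ordered
    stably by panel position when a top-*n* set is taken.
    """

    method: str
    snp_ids: list[str]
    scores: np.ndarray
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.snp_ids) != self.scores.size:
            raise ValueError("scores do not match snp_ids")

    @property
    def _rank_key(self) -> np.ndarray:
        return np.abs(self.scores) if self.method == "olden" else self.scores

    @property
    def ranks(self) -> np.ndarray:
        """Dense ranking, 1 = highest-scoring SNP."""
        return rankdata(-self._rank_key, method="dense").astype(int)

    def top(self, n: int) -> list[str]:
        """The ``n`` best-ranked SNP ids, ties broken by panel order."""
        if n > len(self.snp_ids):
            raise ValueError(f"top {n} requested from a {len(self.snp_ids)}-SNP ranking")
        order = np.argsort(-self._rank_key, kind="stable")
        return [self.snp_ids[i] for i in order[:n]]

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "method": self.method,
                "score": self.scores,
                "rank": self.ranks,
                "selected": [int(s in sel) for s in self.snp_ids],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ImportanceRanking":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
        method = str(df["method"].iloc[0])
        selected = [str(s) for s, f in zip(df["snp_id"], df["selected"]) if f]
        return cls(method, [str(s) for s in df["snp_id"]], df["score"].to_numpy(), selected)


# ---------------------------------------------------------------------------
# importance readouts


def dnn_importance(net: NetworkWeights) -> np.ndarray:
    """Max absolute first-hidden-layer weight per input."""
    if net.n_hidden_layers < 1:
        raise ValueError("network has no hidden layer")
    return np.abs(net.first_layer).max(axis=1)


def selection_threshold(net: NetworkWeights, statistic: str = "pooled") -> float:
    """mean(|W|) + sd(|W|) of first-layer weight magnitudes.

    With ``statistic='pooled'`` (default) every first-layer weight enters
    one empirical distribution; ``'per_input_max'`` instead takes the mean
    and sd over the per-input maximum magnitudes (the same quantities the
    selection rule compares against). The standard deviation is the
    population form (ddof=0) in both cases. An input is selected when its
    :func:`dnn_importance` strictly exceeds this value.
    """
    W = np.abs(net.first_layer)
    if W.size == 0:
        raise ValueError("empty first-layer weight matrix")
    if statistic == "pooled":
        pass
    elif statistic == "per_input_max":
        W = W.max(axis=1)
    else:
        raise ValueError(f"unknown threshold statistic {statistic!r}")
    return float(W.mean() + W.std())


def _require_single_hidden(net: NetworkWeights, method: str) -> None:
    if net.n_hidden_layers != 1:
        raise ValueError(
            f"{method} importance is defined for single-hidden-layer networks; "
            f"this network has {net.n_hidden_layers} hidden layers"
        )


def garson_importance(net: NetworkWeights) -> np.ndarray:
    """Garson/Goh relative importances (non-negative, summing to 1).

    For input *i*, hidden *h*, output *o*: the contribution
    ``|w_ih| |v_ho| / sum_i' |w_i'h|`` is summed over hidden units and
    normalized over inputs; multiple outputs are averaged after per-output
    normalization. Hidden units with all-zero incoming weights contribute
    0 rather than NaN.
    """
    _require_single_hidden(net, "garson")
    W = np.abs(net.weights[0])  # inputs x hidden
    V = np.abs(net.weights[1])  # hidden x outputs
    col_sum = W.sum(axis=0)
    share = np.divide(W, col_sum, out=np.zeros_like(W), where=col_sum > 0)
    contrib = share @ V  # inputs x outputs
    totals = contrib.sum(axis=0)
    live = totals > 0
    if not live.any():  # fully degenerate (all-zero) network
        return np.zeros(W.shape[0])
    # average per-output importances over outputs that receive any signal,
    # so the scores still sum to 1
    per_out = contrib[:, live] / totals[live]
    return per_out.mean(axis=1)


def olden_importance(net: NetworkWeights) -> np.ndarray:
    """Olden connection-weight importances (signed).

    ``sum_h w_ih v_ho`` per input, averaged over outputs when the network
    has several.
    """
    _require_single_hidden(net, "olden")
    return (net.weights[0] @ net.weights[1]).mean(axis=1)


_IMPORTANCE = {
    "dnn": dnn_importance,
    "garson": garson_importance,
    "olden": olden_importance,
}


# ---------------------------------------------------------------------------
# genome-wide selection


def default_training_config(method: str, seed: int = 0, **overrides) -> TrainingConfig:
    """Method-appropriate defaults: two hidden layers (40, 38) with one-hot
    outputs for dnn; one hidden layer of 40 with a single scaled-class
    output for garson/olden."""
    if method == "dnn":
        base = dict(hidden_layers=(40, 38), output_mode="one_hot")
    else:
        base = dict(hidden_layers=(40,), output_mode="scaled_class_index")
    base.update(overrides)
    return TrainingConfig(seed=seed, **base)


def select_snps(
    G: GenotypeMatrix,
    method: str,
    cfg: TrainingConfig | None = None,
    chunk_size: int = 1000,
    n_iterations: int = 1,
    top_k: int | None = None,
    threshold_statistic: str = "pooled",
) -> ImportanceRanking:
    """Train per-chunk networks and build a genome-wide importance ranking.

    For ``method='dnn'`` the mean+sd threshold is applied within each
    chunk's network and the selected set is the union over chunks; for
    garson/olden the selected set is the global top ``top_k`` (no selection
    recorded when ``top_k`` is None). ``n_iterations > 1`` retrains each
    chunk with fresh seeds and averages scores (and, for dnn, thresholds)
    across iterations before selecting.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if cfg is None:
        cfg = default_training_config(method)
    n_classes = len(set(G.breeds))
    if G.n_samples < (n_classes if cfg.output_mode == "one_hot" else 2):
        raise ValueError(
            f"{G.n_samples} samples are too few to train against {n_classes} breeds"
        )
    scorer = _IMPORTANCE[method]
    chunks = partition_snps(G, chunk_size)
    all_scores: list[np.ndarray] = []
    all_selected: list[str] = []
    for c, chunk in enumerate(chunks):
        score_sum = np.zeros(chunk.n_snps)
        tau_sum = 0.0
        for it in range(n_iterations):
            it_cfg = TrainingConfig(
                hidden_layers=cfg.hidden_layers,
                activation=cfg.activation,
                output_mode=cfg.output_mode,
                learning_rate=cfg.learning_rate,
                max_epochs=cfg.max_epochs,
                convergence_tol=cfg.convergence_tol,
                seed=cfg.seed + 7919 * c + it,
            )
            net, _ = train_network(chunk, cfg=it_cfg)
            score_sum += scorer(net)
            if method == "dnn":
                tau_sum += selection_threshold(net, statistic=threshold_statistic)
        scores = score_sum / n_iterations
        all_scores.append(scores)
        if method == "dnn":
            tau = tau_sum / n_iterations
            all_selected.extend(
                sid for sid, s in zip(chunk.snp_ids, scores) if s > tau
            )
    ranking = ImportanceRanking(method, list(G.snp_ids), np.concatenate(all_scores))
    if method == "dnn":
        ranking.selected = all_selected
    elif top_k is not None:
        ranking.selected = ranking.top(top_k)
    return ranking


# ---------------------------------------------------------------------------
# ranking comparison


def compare_rankings(rankings: list[ImportanceRanking], top_n: int = 460) -> pd.DataFrame:
    """Pairwise top-``top_n`` overlap counts and Spearman correlations.

    For each method pair: the number of SNPs shared by the two top-``top_n``
    sets, and the Spearman rank correlation of the two methods' scores over
    that common subset (NaN when the subset has fewer than 2 SNPs — an
    undefined correlation is reported as undefined, never as 0).
    """
    if not 2 <= len(rankings) <= 3:
        raise ValueError("expected 2 or 3 rankings to compare")
    universe = set(rankings[0].snp_ids)
    for r in rankings[1:]:
        if set(r.snp_ids) != universe:
            raise ValueError("rankings cover different SNP universes")
    rows = []
    for ra, rb in combinations(rankings, 2):
        top_a, top_b = set(ra.top(top_n)), set(rb.top(top_n))
        common = top_a & top_b
        if len(common) >= 2:
            sa = {s: x for s, x in zip(ra.snp_ids, ra._rank_key)}
            sb = {s: x for s, x in zip(rb.snp_ids, rb._rank_key)}
            ordered = sorted(common)
            rho = float(spearmanr([sa[s] for s in ordered], [sb[s] for s in ordered]).statistic)
        else:
            rho = float("nan")
        rows.append(
            {
                "method_a": ra.method,
                "method_b": rb.method,
                "top_n": top_n,
                "common": len(common),
                "spearman": rho,
            }
        )
    return pd.DataFrame(rows)
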