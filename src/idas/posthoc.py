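"""Post-hoc differential expression with empirical-Bayes variance moderation.

After classification, each category gets its own contrast analysis on the
pseudobulk matrix:

* ``cellstate_markers`` — one-vs-rest contrasts per cell state on the
  F1-category genes (cell-state markers);
* ``phenotype_signature`` — phenotype level-vs-level contrast on the
  F2-category genes, labeled up/down at configurable (p, fold-change)
  thresholds;
* ``interaction_markers`` — two-step extraction on the interaction genes:
  top-k cell-state markers first, then a phenotype contrast within each
  state to find cell-state-specific phenotype markers.

Variance moderation follows the standard hierarchical model: per-gene
residual variances s2_g on d_g df are assumed scaled inverse-chi-square
around a prior (d0, s0^2), estimated by method of moments on log s2_g; the
posterior variance (d0*s0^2 + d*s2)/(d0 + d) feeds a t-statistic with
d0 + d degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .classify import adjust_bh
from .datatypes import DEResult, PseudobulkMatrix

logger = logging.getLogger(__name__)

DEFAULT_P_CUT = 0.001
DEFAULT_FC_CUT = float(np.log2(1.5))


@dataclass(frozen=True)
class ModerationParams:
    """Prior of the variance hierarchy: d0 (possibly inf) and s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def fit_contrast(values: np.ndarray, group1: np.ndarray, group0: np.ndarray,
                 gene_ids: list[str]) -> pd.DataFrame:
    """Two-group OLS contrast per gene: estimate, residual variance, df.

    ``group1``/``group0`` are boolean masks over observations. Returns a
    frame with ``log2fc`` (mean difference group1 - group0), pooled
    residual variance ``s2`` on ``df = n - 2`` degrees of freedom, and the
    unscaled contrast variance ``v = 1/n1 + 1/n0``.
    """
    group1 = np.asarray(group1, bool)
    group0 = np.asarray(group0, bool)
    if group1.sum() < 1 or group0.sum() < 1:
        raise ValueError("each contrast side needs at least one observation")
    if np.any(group1 & group0):
        raise ValueError("contrast sides overlap")
    n1, n0 = int(group1.sum()), int(group0.sum())
    y1, y0 = values[:, group1], values[:, group0]
    m1, m0 = y1.mean(axis=1), y0.mean(axis=1)
    rss = ((y1 - m1[:, None]) ** 2).sum(axis=1) + ((y0 - m0[:, None]) ** 2).sum(axis=1)
    d = n1 + n0 - 2
    if d < 1:
        raise ValueError("contrast has no residual degrees of freedom")
    return pd.DataFrame(
        {
            "log2fc": m1 - m0,
            "s2": rss / d,
            "df": float(d),
            "v": 1.0 / n1 + 1.0 / n0,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_moderation(s2: np.ndarray, df: np.ndarray,
                        min_genes: int = 10) -> ModerationParams:
    """Method-of-moments fit of the variance prior on log residual variances.

    Under the hierarchy, z = log s2 has mean log s0^2 + digamma(d/2) -
    log(d/2) and variance trigamma(d/2) + trigamma(d0/2); matching the
    empirical moments of z gives (d0, s0^2). When the empirical variance of
    z does not exceed its sampling expectation, d0 = inf (all genes share
    one variance). Zero variances are excluded from estimation.
    """
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    keep = (s2 > 0) & (df >= 1)
    if keep.sum() < min_genes:
        raise ValueError(
            f"insufficient genes for moderation: {int(keep.sum())} usable, "
            f"need >= {min_genes}")
    s2, df = s2[keep], df[keep]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    elif np.var(z) <= 1e-15:
        # literally identical variances: no sampling noise to correct for
        d0 = np.inf
        s0_sq = float(np.exp(z.mean()))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_t(contrasts: pd.DataFrame, params: ModerationParams) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values for a contrast frame.

    Adds ``s2_post`` (posterior variance), ``t`` and ``p`` columns. With
    d0 = 0 the ordinary per-gene t-test is recovered exactly; with
    d0 = inf every gene is tested against the common prior variance with a
    normal reference.
    """
    out = contrasts.copy()
    d0, s0 = params.d0, params.s0_sq
    d = out["df"].to_numpy(float)
    s2 = out["s2"].to_numpy(float)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * out["v"].to_numpy(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = out["log2fc"].to_numpy(float) / se
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    # zero posterior variance with a nonzero estimate: exact separation
    zero = se == 0
    t = np.where(zero, np.where(out["log2fc"] == 0, 0.0, np.inf * np.sign(out["log2fc"])), t)
    p = np.where(zero, np.where(out["log2fc"] == 0, 1.0, 0.0), p)
    if zero.any():
        logger.warning("%d gene(s) with zero residual variance; p set to 0", int(zero.sum()))
    out["s2_post"] = s2_post
    out["t"] = t
    out["p"] = p
    return out


def _de_table(values: np.ndarray, gene_ids: list[str], g1: np.ndarray, g0: np.ndarray,
              contrast: str, params: ModerationParams | None = None) -> pd.DataFrame:
    con = fit_contrast(values, g1, g0, gene_ids)
    if params is None:
        try:
            params = estimate_moderation(con["s2"].to_numpy(), con["df"].to_numpy())
        except ValueError:
            # too few genes to learn a prior: fall back to ordinary t
            params = ModerationParams(d0=0.0, s0_sq=1.0)
    mod = moderated_t(con, params)
    mod["padj"] = adjust_bh(mod["p"].to_numpy())
    mod.insert(0, "contrast", contrast)
    return mod.reset_index()


def _subset(pb: PseudobulkMatrix, genes: list[str]) -> tuple[np.ndarray, list[str]]:
    idx = [pb.gene_ids.index(g) for g in genes]
    return pb.values[idx], list(genes)


def cellstate_markers(pb: PseudobulkMatrix, genes: list[str],
                      min_obs: int = 2) -> DEResult:
    """One-vs-rest moderated-t contrasts per cell-state level (factor f1).

    BH adjustment is within each state. States with fewer than ``min_obs``
    observations are skipped with a warning. Positive markers are rows with
    ``log2fc > 0``.
    """
    if len(genes) == 0:
        raise ValueError("no genes to test")
    states = pb.design.levels("f1")
    if len(states) < 2:
        raise ValueError("one-vs-rest contrasts need >= 2 cell states")
    values, gids = _subset(pb, genes)
    f1 = pb.design.f1.astype(str)
    frames = []
    for s in states:
        g1 = f1 == s
        if g1.sum() < min_obs:
            logger.warning("state %r has %d observation(s); skipped", s, int(g1.sum()))
            continue
        frames.append(_de_table(values, gids, g1, ~g1, contrast=f"{s}_vs_rest"))
    if not frames:
        raise ValueError("no state had enough observations")
    table = pd.concat(frames, ignore_index=True)
    table["positive_marker"] = table["log2fc"] > 0
    return DEResult(table=table)


def phenotype_signature(pb: PseudobulkMatrix, genes: list[str],
                        p_cut: float = DEFAULT_P_CUT,
                        fc_cut: float = DEFAULT_FC_CUT) -> DEResult:
    """Signed phenotype contrast (factor f2, exactly two levels).

    Genes are labeled ``up-in-<level2>`` / ``up-in-<level1>`` /
    ``below-threshold`` using raw p < ``p_cut`` and |log2FC| > ``fc_cut``.
    """
    if len(genes) == 0:
        raise ValueError("no genes to test")
    levels = pb.design.levels("f2")
    if len(levels) != 2:
        raise ValueError(
            f"signed phenotype report requires exactly 2 levels, got {levels}")
    values, gids = _subset(pb, genes)
    f2 = pb.design.f2.astype(str)
    table = _de_table(values, gids, f2 == levels[1], f2 == levels[0],
                      contrast=f"{levels[1]}_vs_{levels[0]}")
    passed = (table["p"] < p_cut) & (table["log2fc"].abs() > fc_cut)
    table["label"] = np.where(
        ~passed, "below-threshold",
        np.where(table["log2fc"] > 0, f"up-in-{levels[1]}", f"up-in-{levels[0]}"))
    return DEResult(table=table)


def interaction_markers(pb: PseudobulkMatrix, genes: list[str], top_k: int = 10,
                        p_cut: float = DEFAULT_P_CUT,
                        fc_cut: float = DEFAULT_FC_CUT) -> DEResult:
    """Cell-state-specific phenotype markers from the interaction gene set.

    Step 1 ranks the interaction genes within each cell state by
    one-vs-rest moderated-t p (ties by |log2FC| descending, then gene id)
    and keeps the top ``top_k``. Step 2 contrasts the two phenotypes within
    that state's observations for the kept genes. The result reports every
    (gene, state) pair with a ``specific`` flag marking pairs passing
    (p_cut, fc_cut); states observed under a single phenotype are skipped.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    markers = cellstate_markers(pb, genes, min_obs=1)
    f1 = pb.design.f1.astype(str)
    f2 = pb.design.f2.astype(str)
    levels2 = pb.design.levels("f2")
    if len(levels2) != 2:
        raise ValueError("interaction markers require exactly 2 phenotype levels")
    frames = []
    for s in pb.design.levels("f1"):
        sub = markers.table[markers.table["contrast"] == f"{s}_vs_rest"].copy()
        if sub.empty:
            continue
        sub["absfc"] = sub["log2fc"].abs()
        sub = sub.sort_values(["p", "absfc", "gene_id"],
                              ascending=[True, False, True])
        kept = list(sub["gene_id"].head(top_k))
        in_state = f1 == s
        present = {lev for lev in f2[in_state]}
        if len(present) < 2:
            logger.warning("state %r observed under one phenotype; skipped", s)
            continue
        g1 = in_state & (f2 == levels2[1])
        g0 = in_state & (f2 == levels2[0])
        if g1.sum() + g0.sum() < 3:
            logger.warning("state %r has too few observations for a within-state "
                           "contrast; skipped", s)
            continue
        values, gids = _subset(pb, kept)
        tab = _de_table(values, gids, g1, g0,
                        contrast=f"{s}:{levels2[1]}_vs_{levels2[0]}")
        tab["state"] = s
        frames.append(tab)
    if not frames:
        raise ValueError("no state had both phenotypes represented")
    table = pd.concat(frames, ignore_index=True)
    table["specific"] = (table["p"] < p_cut) & (table["log2fc"].abs() > fc_cut)
    table["phenotype"] = np.where(table["log2fc"] > 0, levels2[1], levels2[0])
    return DEResult(table=table)
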