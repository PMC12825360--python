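"""Staged nested-ANOVA classification of genes into effect categories.

Two-way fixed-effect route (five categories)::

    stage 1  no-effect test   null vs full          -> non-sig | significant
    stage 2  interaction      additive vs full      -> F1xF2
    stage 3  main effects     single-factor vs additive -> F1 | F2
    stage 4  remainder                               -> F1+F2

Three-way random-intercept route (ten categories) follows the same logic
with the all-two-way and single-factor models in between; see
:func:`classify_three_way`.

Benjamini-Hochberg adjustment is applied within each stage across exactly
the genes entering that stage. The stage-1 threshold may be a fixed level
or a p-value quantile ("top q% of genes"); later stages always use a fixed
level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    THREE_WAY_CATEGORIES,
    TWO_WAY_CATEGORIES,
    GeneClassification,
    PseudobulkMatrix,
)
from .models import (
    THREE_WAY_SPECS,
    TWO_WAY_SPECS,
    FitResult,
    f_test_nested,
    fit_fixed,
    fit_mixed,
    lrt_nested,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdPolicy:
    """How stage p-values are turned into significance calls.

    ``mode="alpha"`` compares each (adjusted) p-value against ``level``;
    ``mode="quantile"`` declares the floor(level * m) genes with the
    smallest (adjusted) p-values significant — applicable only to the
    stage-1 no-effect test. Later stages use ``stage_level`` (defaults to
    ``level`` in alpha mode, 0.05 in quantile mode).
    """

    mode: str = "alpha"
    level: float = 0.05
    use_adjusted: bool = True
    stage_level: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("alpha", "quantile"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")

    @property
    def later_stage_level(self) -> float:
        if self.stage_level is not None:
            return self.stage_level
        return self.level if self.mode == "alpha" else 0.05


def adjust_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_significant(pvals: pd.Series, policy: ThresholdPolicy,
                       adjusted: Optional[pd.Series] = None) -> pd.Series:
    """Boolean significance calls for a stage-1 style p-value vector.

    ``pvals`` raw p indexed by gene id; ``adjusted`` the matching BH values
    (computed here if omitted). Quantile-mode boundary ties break by gene-id
    lexicographic order so the selection is deterministic.
    """
    if len(pvals) == 0:
        raise ValueError("empty p-value vector")
    if adjusted is None:
        adjusted = pd.Series(adjust_bh(pvals.to_numpy()), index=pvals.index)
    used = adjusted if policy.use_adjusted else pvals
    if policy.mode == "alpha":
        return used <= policy.level
    k = int(np.floor(policy.level * len(used)))
    order = sorted(used.index, key=lambda g: (used[g], str(g)))
    chosen = set(order[:k])
    return pd.Series([g in chosen for g in used.index], index=used.index)


def _alpha_calls(p: pd.Series, level: float, use_adjusted: bool) -> tuple[pd.Series, pd.Series]:
    """(adjusted p, boolean calls) at a fixed level for a later-stage test."""
    padj = pd.Series(adjust_bh(p.to_numpy()), index=p.index)
    used = padj if use_adjusted else p
    return padj, used <= level


class _StageTable:
    """Accumulates per-stage raw/adjusted p-values over a growing gene set."""

    def __init__(self, gene_ids: list[str]):
        self.gene_ids = gene_ids
        self.cols: dict[str, pd.Series] = {}

    def record(self, stage: str, p: pd.Series, padj: pd.Series) -> None:
        self.cols[f"{stage}.p"] = p
        self.cols[f"{stage}.padj"] = padj

    def build(self, categories: pd.Series) -> pd.DataFrame:
        df = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        df["category"] = categories
        for name, col in self.cols.items():
            df[name] = col.reindex(df.index)
        return df


def _safe_test(test: Callable[[], float]) -> tuple[float, Optional[str]]:
    try:
        return test(), None
    except (ValueError, np.linalg.LinAlgError) as exc:
        return np.nan, str(exc)


def classify_two_way(pb: PseudobulkMatrix, policy: ThresholdPolicy) -> GeneClassification:
    """Five-category classification on a two-factor fixed-effect design.

    Genes whose stage tests are untestable (residual df exhausted by
    missing values or incomplete designs) fall to non-sig with a reason
    code, so the categories always partition the gene set. Zero-variance
    genes carry p = 1 at every stage.
    """
    design = pb.design
    if design.is_three_way:
        raise ValueError("design has three factors; use classify_three_way")
    design.require_two_levels()
    genes = list(pb.gene_ids)
    stage = _StageTable(genes)
    category = pd.Series("non-sig", index=pd.Index(genes, name="gene_id"))
    reasons: dict[str, str] = {}

    fits: dict[str, dict[str, FitResult]] = {}
    p1 = {}
    for g, y in zip(genes, pb.values):
        mask = np.isfinite(y)
        if mask.sum() < 3 or np.allclose(y[mask], y[mask][0] if mask.any() else 0.0):
            p1[g] = 1.0
            reasons[g] = "zero-variance" if mask.sum() >= 3 else "too-few-observations"
            fits[g] = {}
            continue
        f = {name: fit_fixed(y, design, spec_, mask=mask)
             for name, spec_ in TWO_WAY_SPECS.items()}
        fits[g] = f
        pv, err = _safe_test(lambda: f_test_nested(f["full"], f["null"]))
        if err is not None:
            reasons[g] = f"untestable: {err}"
        p1[g] = pv

    p1 = pd.Series(p1, name="no_effect")
    tested = p1.dropna().index
    padj1 = pd.Series(adjust_bh(p1.loc[tested].to_numpy()), index=tested).reindex(p1.index)
    stage.record("no_effect", p1, padj1)
    sig = select_significant(p1.loc[tested], policy, adjusted=padj1.loc[tested])
    c_sig = [g for g in tested if sig[g] and reasons.get(g) != "zero-variance"]
    logger.info("stage 1: %d / %d genes significant", len(c_sig), len(genes))

    level = policy.later_stage_level
    if c_sig:
        p_int = pd.Series(
            {g: _safe_test(lambda: f_test_nested(fits[g]["full"], fits[g]["additive"]))[0]
             for g in c_sig})
        ok = p_int.dropna().index
        padj_int, call_int = _alpha_calls(p_int.loc[ok], level, policy.use_adjusted)
        stage.record("interaction", p_int, padj_int.reindex(p_int.index))
        c_inter = [g for g in ok if call_int[g]]
        category.loc[c_inter] = "F1xF2"
        for g in p_int.index.difference(ok):
            reasons[g] = reasons.get(g, "untestable: interaction stage")
        remaining = [g for g in c_sig if g in ok and g not in c_inter]
        logger.info("stage 2: %d interaction genes", len(c_inter))

        if remaining:
            p_a = pd.Series(
                {g: _safe_test(lambda: f_test_nested(fits[g]["additive"], fits[g]["f2_only"]))[0]
                 for g in remaining})
            p_b = pd.Series(
                {g: _safe_test(lambda: f_test_nested(fits[g]["additive"], fits[g]["f1_only"]))[0]
                 for g in remaining})
            ok_a, ok_b = p_a.dropna().index, p_b.dropna().index
            padj_a, call_a = _alpha_calls(p_a.loc[ok_a], level, policy.use_adjusted)
            padj_b, call_b = _alpha_calls(p_b.loc[ok_b], level, policy.use_adjusted)
            stage.record("main_f1", p_a, padj_a.reindex(p_a.index))
            stage.record("main_f2", p_b, padj_b.reindex(p_b.index))
            for g in remaining:
                if g not in ok_a or g not in ok_b:
                    reasons[g] = reasons.get(g, "untestable: main-effect stage")
                    continue
                a = bool(call_a[g])
                b = bool(call_b[g])
                if a and not b:
                    category.loc[g] = "F1"
                elif b and not a:
                    category.loc[g] = "F2"
                else:
                    category.loc[g] = "F1+F2"
    table = stage.build(category)
    gc = GeneClassification(
        table=table,
        threshold_mode=policy.mode,
        level=policy.level,
        use_adjusted=policy.use_adjusted,
        categories=TWO_WAY_CATEGORIES,
        reasons=reasons,
    )
    assert gc.counts().sum() == len(genes), "categories must partition the gene set"
    return gc


def classify_three_way(pb: PseudobulkMatrix, policy: ThresholdPolicy) -> GeneClassification:
    """Ten-category classification on a three-factor random-intercept design.

    All fits are maximum likelihood with a subject random intercept; nested
    comparisons use the chi-square likelihood-ratio test. Stage 3 assigns a
    single-factor category only when exactly one single-factor model is NOT
    contradicted (its own test non-significant) while the other two are;
    genes with ambiguous patterns go to the additive category.
    """
    design = pb.design
    if not design.is_three_way:
        raise ValueError("design has no third factor; use classify_two_way")
    if design.subject is None:
        raise ValueError("three-way classification requires a subject grouping")
    design.require_two_levels()
    genes = list(pb.gene_ids)
    stage = _StageTable(genes)
    category = pd.Series("non-sig", index=pd.Index(genes, name="gene_id"))
    reasons: dict[str, str] = {}
    level = policy.later_stage_level

    cache: dict[str, dict[str, FitResult]] = {g: {} for g in genes}
    masks = {g: np.isfinite(y) for g, y in zip(genes, pb.values)}
    values = {g: y for g, y in zip(genes, pb.values)}

    def fit(g: str, name: str) -> FitResult:
        if name not in cache[g]:
            cache[g][name] = fit_mixed(values[g], design, THREE_WAY_SPECS[name],
                                       mask=masks[g])
        return cache[g][name]

    def lrt(g: str, full: str, reduced: str) -> tuple[float, Optional[str]]:
        return _safe_test(lambda: lrt_nested(fit(g, full), fit(g, reduced)))

    p1 = {}
    for g in genes:
        y, mask = values[g], masks[g]
        if mask.sum() < 3 or np.allclose(y[mask], y[mask][0] if mask.any() else 0.0):
            p1[g] = 1.0
            reasons[g] = "zero-variance" if mask.sum() >= 3 else "too-few-observations"
            continue
        pv, err = lrt(g, "full", "null")
        if err is not None:
            reasons[g] = f"untestable: {err}"
        p1[g] = pv
    p1 = pd.Series(p1)
    tested = p1.dropna().index
    padj1 = pd.Series(adjust_bh(p1.loc[tested].to_numpy()), index=tested).reindex(p1.index)
    stage.record("no_effect", p1, padj1)
    sig = select_significant(p1.loc[tested], policy, adjusted=padj1.loc[tested])
    c_sig = [g for g in tested if sig[g] and reasons.get(g) != "zero-variance"]
    logger.info("stage 1: %d / %d genes significant", len(c_sig), len(genes))

    if c_sig:
        p_int = pd.Series({g: lrt(g, "full", "additive")[0] for g in c_sig})
        ok = p_int.dropna().index
        padj_int, call_int = _alpha_calls(p_int.loc[ok], level, policy.use_adjusted)
        stage.record("interaction", p_int, padj_int.reindex(p_int.index))
        for g in p_int.index.difference(ok):
            reasons.setdefault(g, "untestable: interaction stage")
        c_int = [g for g in ok if call_int[g]]
        c_notint = [g for g in ok if not call_int[g]]
        logger.info("stage 2: %d interaction / %d non-interaction", len(c_int), len(c_notint))

        # stage 3/4: single-factor patterns within the non-interaction set
        if c_notint:
            single = {"main_f1": "f1_only", "main_f2": "f2_only", "main_f3": "f3_only"}
            calls = {}
            for test_name, reduced in single.items():
                p = pd.Series({g: lrt(g, "additive", reduced)[0] for g in c_notint})
                okg = p.dropna().index
                padj, call = _alpha_calls(p.loc[okg], level, policy.use_adjusted)
                stage.record(test_name, p, padj.reindex(p.index))
                calls[test_name] = call
            for g in c_notint:
                if any(g not in calls[t].index for t in calls):
                    reasons[g] = reasons.get(g, "untestable: main-effect stage")
                    continue
                pattern = tuple(bool(calls[t][g]) for t in
                                ("main_f1", "main_f2", "main_f3"))
                if pattern == (False, True, True):
                    category.loc[g] = "F1"
                elif pattern == (True, False, True):
                    category.loc[g] = "F2"
                elif pattern == (True, True, False):
                    category.loc[g] = "F3"
                else:
                    category.loc[g] = "additive"
                    if sum(not c for c in pattern) > 1:
                        reasons[g] = "ambiguous-main"

        # stage 5: three-way interaction within the interaction set
        if c_int:
            p3 = pd.Series({g: lrt(g, "full", "all_two_way")[0] for g in c_int})
            ok3 = p3.dropna().index
            padj3, call3 = _alpha_calls(p3.loc[ok3], level, policy.use_adjusted)
            stage.record("three_way", p3, padj3.reindex(p3.index))
            c_three = [g for g in ok3 if call3[g]]
            category.loc[c_three] = "F1xF2xF3"
            c_two = [g for g in ok3 if not call3[g]]

            # stage 6: which two-way interaction(s)
            if c_two:
                pairwise = {"int_f1f2": "no_f1f2", "int_f2f3": "no_f2f3",
                            "int_f1f3": "no_f1f3"}
                calls2 = {}
                for test_name, reduced in pairwise.items():
                    p = pd.Series({g: lrt(g, "all_two_way", reduced)[0] for g in c_two})
                    okg = p.dropna().index
                    padj, call = _alpha_calls(p.loc[okg], level, policy.use_adjusted)
                    stage.record(test_name, p, padj.reindex(p.index))
                    calls2[test_name] = call
                for g in c_two:
                    if any(g not in calls2[t].index for t in calls2):
                        reasons[g] = reasons.get(g, "untestable: two-way stage")
                        continue
                    pattern = tuple(bool(calls2[t][g]) for t in
                                    ("int_f1f2", "int_f2f3", "int_f1f3"))
                    if pattern == (True, False, False):
                        category.loc[g] = "F1xF2"
                    elif pattern == (False, True, False):
                        category.loc[g] = "F2xF3"
                    elif pattern == (False, False, True):
                        category.loc[g] = "F1xF3"
                    else:
                        category.loc[g] = "two-way-combine"

    table = stage.build(category)
    gc = GeneClassification(
        table=table,
        threshold_mode=policy.mode,
        level=policy.level,
        use_adjusted=policy.use_adjusted,
        categories=THREE_WAY_CATEGORIES,
        reasons=reasons,
    )
    assert gc.counts().sum() == len(genes), "categories must partition the gene set"
    return gc
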