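"""Synthetic factorial expression data with known per-gene ground truth.

Every generator plants genes in a named category by drawing its effect
offsets from centered normals and re-centering them to sum to zero within
each factor (interaction tables are centered across every margin), so a
gene's category is identifiable from which offset sets are nonzero. The
response is the category's own factorial model plus Gaussian noise (plus a
subject random intercept in the three-way design). All draws flow from a
single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    THREE_WAY_CATEGORIES,
    TWO_WAY_CATEGORIES,
    GeneClassification,
    ObservationDesign,
    PseudobulkMatrix,
    SingleCellDataset,
)


@dataclass
class SimTruth:
    """Planted category and effect parameters per gene."""

    table: pd.DataFrame  # gene_id index, 'category' column
    effects: dict[str, dict] = field(default_factory=dict)
    noise_sd: float = 1.0
    subject_sd: float = 0.0
    seed: int = 0

    def category_of(self, gene: str) -> str:
        return str(self.table.loc[gene, "category"])


def _centered(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """Offsets with every one-dimensional margin summing to zero."""
    x = rng.normal(0.0, sd, size=shape)
    x = np.atleast_1d(x)
    for axis in range(x.ndim):
        x = x - x.mean(axis=axis, keepdims=True)
    # re-centering shrinks the spread; rescale back to the requested sd
    s = x.std()
    if s > 0:
        x = x * (sd / s)
    return x


def _two_way_effects(rng: np.random.Generator, category: str, I: int, J: int,
                     effect_sd: float) -> dict:
    eff = {"alpha": np.zeros(I), "beta": np.zeros(J), "ab": np.zeros((I, J))}
    if category in ("F1", "F1+F2"):
        eff["alpha"] = _centered(rng, I, effect_sd)
    if category in ("F2", "F1+F2"):
        eff["beta"] = _centered(rng, J, effect_sd)
    if category == "F1xF2":
        eff["ab"] = _centered(rng, (I, J), effect_sd)
    return eff


def simulate_two_way(n_per_category: int = 50, I: int = 3, J: int = 2, m: int = 4,
                     effect_sd: float = 2.0, noise_sd: float = 0.5,
                     baseline: float = 8.0, seed: int = 0,
                     categories: tuple[str, ...] = TWO_WAY_CATEGORIES,
                     ) -> tuple[PseudobulkMatrix, SimTruth]:
    """Balanced two-factor pseudobulk with ``n_per_category`` genes per label."""
    if I < 2 or J < 2 or m < 2:
        raise ValueError("need I, J >= 2 and m >= 2")
    if effect_sd <= 0 or noise_sd <= 0:
        raise ValueError("effect_sd and noise_sd must be positive")
    rng = np.random.default_rng(seed)
    f1 = np.repeat([f"s{i}" for i in range(I)], J * m)
    f2 = np.tile(np.repeat([f"p{j}" for j in range(J)], m), I)
    obs_ids = [f"o{i}_{v1}_{v2}" for i, (v1, v2) in enumerate(zip(f1, f2))]
    design = ObservationDesign(obs_ids=obs_ids, f1=f1, f2=f2)
    ii = np.array([int(v[1:]) for v in f1])
    jj = np.array([int(v[1:]) for v in f2])

    rows, gene_ids, cats, effects = [], [], [], {}
    g = 0
    for cat in categories:
        for _ in range(n_per_category):
            gid = f"g{g:05d}"
            eff = _two_way_effects(rng, cat, I, J, effect_sd)
            mu = baseline + rng.normal(0.0, 1.0)
            y = (mu + eff["alpha"][ii] + eff["beta"][jj] + eff["ab"][ii, jj]
                 + rng.normal(0.0, noise_sd, size=len(ii)))
            rows.append(y)
            gene_ids.append(gid)
            cats.append(cat)
            effects[gid] = eff
            g += 1
    pb = PseudobulkMatrix(values=np.array(rows), gene_ids=gene_ids, design=design)
    truth = SimTruth(
        table=pd.DataFrame({"category": cats},
                           index=pd.Index(gene_ids, name="gene_id")),
        effects=effects, noise_sd=noise_sd, seed=seed)
    return pb, truth


def _three_way_effects(rng: np.random.Generator, category: str, I: int, J: int,
                       K: int, effect_sd: float) -> dict:
    eff = {"alpha": np.zeros(I), "beta": np.zeros(J), "gamma": np.zeros(K),
           "ab": np.zeros((I, J)), "bg": np.zeros((J, K)), "ag": np.zeros((I, K)),
           "abg": np.zeros((I, J, K))}
    mains = {"F1": ["alpha"], "F2": ["beta"], "F3": ["gamma"],
             "additive": ["alpha", "beta", "gamma"]}
    if category in mains:
        for name in mains[category]:
            size = {"alpha": I, "beta": J, "gamma": K}[name]
            eff[name] = _centered(rng, size, effect_sd)
    elif category == "F1xF2":
        eff["ab"] = _centered(rng, (I, J), effect_sd)
    elif category == "F2xF3":
        eff["bg"] = _centered(rng, (J, K), effect_sd)
    elif category == "F1xF3":
        eff["ag"] = _centered(rng, (I, K), effect_sd)
    elif category == "two-way-combine":
        eff["ab"] = _centered(rng, (I, J), effect_sd)
        eff["bg"] = _centered(rng, (J, K), effect_sd)
    elif category == "F1xF2xF3":
        eff["abg"] = _centered(rng, (I, J, K), effect_sd)
    elif category != "non-sig":
        raise ValueError(f"unknown category {category!r}")
    return eff


def simulate_three_way(n_per_category: int = 30, I: int = 3, J: int = 2, K: int = 2,
                       m: int = 1, n_subjects: int = 8, effect_sd: float = 2.0,
                       noise_sd: float = 0.5, subject_sd: float = 0.5,
                       baseline: float = 8.0, seed: int = 0,
                       categories: tuple[str, ...] = THREE_WAY_CATEGORIES,
                       nest_subjects_in_f2: bool = False,
                       ) -> tuple[PseudobulkMatrix, SimTruth]:
    """Three-factor pseudobulk with a subject random intercept.

    By default every subject is observed in every (f1, f2, f3) combination
    with ``m`` replicates — the exchangeable random-intercept structure of
    the factorial models under test, where the subject intercept is crossed
    with all factors. ``nest_subjects_in_f2=True`` instead gives each
    subject a single f2 level (a patient has one phenotype, as in a
    treatment-response study); note that testing a between-subject factor
    by chi-square LRT with few subjects is anti-conservative, which is a
    property of the procedure, not of the generator.
    """
    if min(I, J, K) < 2 or m < 1:
        raise ValueError("need I, J, K >= 2 and m >= 1")
    if n_subjects < (2 * J if nest_subjects_in_f2 else 2):
        raise ValueError("too few subjects for the requested design")
    rng = np.random.default_rng(seed)
    recs = []
    for s in range(n_subjects):
        jlevels = [s % J] if nest_subjects_in_f2 else range(J)
        for j in jlevels:
            for i in range(I):
                for k in range(K):
                    for r in range(m):
                        recs.append((f"t{i}", f"p{j}", f"c{k}", f"sub{s}", r))
    df = pd.DataFrame(recs, columns=["f1", "f2", "f3", "subject", "rep"])
    obs_ids = [f"o{n}_{r.f1}_{r.f2}_{r.f3}_{r.subject}"
               for n, r in enumerate(df.itertuples())]
    design = ObservationDesign(obs_ids=obs_ids, f1=df["f1"].to_numpy(),
                               f2=df["f2"].to_numpy(), f3=df["f3"].to_numpy(),
                               subject=df["subject"].to_numpy())
    ii = df["f1"].str[1:].astype(int).to_numpy()
    jj = df["f2"].str[1:].astype(int).to_numpy()
    kk = df["f3"].str[1:].astype(int).to_numpy()
    ss = df["subject"].str[3:].astype(int).to_numpy()

    rows, gene_ids, cats, effects = [], [], [], {}
    g = 0
    for cat in categories:
        for _ in range(n_per_category):
            gid = f"g{g:05d}"
            eff = _three_way_effects(rng, cat, I, J, K, effect_sd)
            mu = baseline + rng.normal(0.0, 1.0)
            u = rng.normal(0.0, subject_sd, size=n_subjects)
            y = (mu + eff["alpha"][ii] + eff["beta"][jj] + eff["gamma"][kk]
                 + eff["ab"][ii, jj] + eff["bg"][jj, kk] + eff["ag"][ii, kk]
                 + eff["abg"][ii, jj, kk] + u[ss]
                 + rng.normal(0.0, noise_sd, size=len(ii)))
            rows.append(y)
            gene_ids.append(gid)
            cats.append(cat)
            effects[gid] = eff
            g += 1
    pb = PseudobulkMatrix(values=np.array(rows), gene_ids=gene_ids, design=design)
    truth = SimTruth(
        table=pd.DataFrame({"category": cats},
                           index=pd.Index(gene_ids, name="gene_id")),
        effects=effects, noise_sd=noise_sd, subject_sd=subject_sd, seed=seed)
    return pb, truth


def simulate_single_cell(samples: dict[str, str], states: list[str],
                         cells_per_group: int = 100,
                         gene_programs: dict[str, dict[tuple[str, str], float]] | None = None,
                         noise_sigma: float = 0.5, seed: int = 0) -> SingleCellDataset:
    """Single-cell counts around planted (sample, state) group means.

    ``samples`` maps sample id -> phenotype; ``gene_programs`` maps gene id
    to a (sample, state) -> mean table (missing groups default to 1.0).
    Cell values are mean-preserving lognormal: mean * exp(sigma*Z - sigma^2/2),
    so aggregated pseudobulk converges to log2(mean + pseudocount).
    """
    if not samples or not states:
        raise ValueError("need at least one sample and one state")
    if gene_programs is None:
        gene_programs = {"g0": {}}
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_programs)
    cell_ids, meta_rows, cols = [], [], []
    c = 0
    for sample, pheno in samples.items():
        for state in states:
            for _ in range(cells_per_group):
                cell_ids.append(f"cell{c:06d}")
                meta_rows.append({"sample_id": sample, "state": state,
                                  "phenotype": pheno})
                c += 1
            means = np.array([gene_programs[g].get((sample, state), 1.0)
                              for g in gene_ids])
            z = rng.normal(size=(len(gene_ids), cells_per_group))
            vals = means[:, None] * np.exp(noise_sigma * z - noise_sigma ** 2 / 2.0)
            cols.append(vals)
    return SingleCellDataset(
        values=np.concatenate(cols, axis=1),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_meta=pd.DataFrame(meta_rows),
    )


def simulate_spatial(n_pairs: int = 200, rho: float = 0.5, n_genes: int = 1,
                     seed: int = 0, jitter: float = 0.1,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Cells in tight spatial pairs with controlled neighbor correlation.

    Pairs sit on a coarse grid (spacing 3) with the two cells of a pair one
    unit apart plus a small jitter, so each cell's nearest neighbor is its
    partner. Per gene, pair expression is bivariate normal with correlation
    ``rho``; the realized nnCorrelation converges to rho as pairs grow.
    Returns (values genes x cells, coords cells x 2).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    if n_pairs < 2:
        raise ValueError("need >= 2 pairs")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_pairs)))
    coords = []
    for p in range(n_pairs):
        bx, by = 3.0 * (p % side), 3.0 * (p // side)
        coords.append((bx + rng.uniform(-jitter, jitter),
                       by + rng.uniform(-jitter, jitter)))
        coords.append((bx + 1.0 + rng.uniform(-jitter, jitter),
                       by + rng.uniform(-jitter, jitter)))
    coords = np.array(coords)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    z = rng.normal(size=(n_genes, n_pairs, 2)) @ L.T
    values = z.reshape(n_genes, 2 * n_pairs)
    return values, coords


def recovery_metrics(truth: SimTruth, gc: GeneClassification) -> pd.DataFrame:
    """Confusion matrix plus per-category recall/precision and C_sig FDR.

    Returns the confusion matrix (truth rows x predicted columns) with
    ``recall`` and ``precision`` columns appended; the empirical false
    discovery rate of the significant set is in ``.attrs['fdr_sig']``.
    """
    t = truth.table["category"]
    p = gc.table["category"]
    if set(t.index) != set(p.index):
        raise ValueError("truth and classification cover different gene sets")
    p = p.reindex(t.index)
    cats = list(gc.categories)
    conf = pd.crosstab(t, p).reindex(index=cats, columns=cats, fill_value=0)
    diag = np.diag(conf.to_numpy())
    with np.errstate(invalid="ignore"):
        recall = diag / conf.sum(axis=1).to_numpy()
        precision = diag / conf.sum(axis=0).to_numpy()
    out = conf.copy()
    out["recall"] = recall
    out["precision"] = precision
    sig_pred = p != "non-sig"
    n_sig = int(sig_pred.sum())
    false_sig = int(((t == "non-sig") & sig_pred).sum())
    out.attrs["fdr_sig"] = false_sig / n_sig if n_sig else 0.0
    out.attrs["n_sig"] = n_sig
    return out
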