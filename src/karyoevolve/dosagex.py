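"""Dosage-compensation and sex-biased-expression statistics.

When a (neo-)Y degenerates, X-linked genes become hemizygous in males; if no
compensation evolves, male expression of the X strata falls to half the
female level, while full compensation restores parity with autosomes and
with the ancestral (proto-X) expression level.  This module provides the
statistics used to read those signatures out of FPKM-like expression
matrices: an expressed-gene filter (FPKM >= 1 in either group), Wilcoxon
rank-sum comparisons with Bonferroni correction and letter groups,
stratum-wise male/female medians, a paired neo-X vs proto-X comparison
against an outgroup where the neo-X is still autosomal, a strict >2-fold
rule for gonad-biased genes, and hypergeometric enrichment/depletion tests
of biased genes per chromosome stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DosageResult",
    "partition_genes",
    "select_samples",
    "filter_expressed",
    "wilcoxon_rank_sum",
    "hypergeometric_tail",
    "dosage_compare",
    "proto_vs_neo",
    "classify_gonad_bias",
    "test_enrichment",
]

STRATA_ORDER = ("autosome", "anc-X", "neo-X", "X", "Y")


def partition_genes(
    genes: pd.DataFrame,
    x_chrom: Union[str, Sequence[str]],
    breakpoint_bp: int | None = None,
    anc_side: str = "left",
    y_chroms: Sequence[str] = (),
) -> pd.Series:
    """Assign each gene to a chromosome stratum from coordinates.

    Genes on ``x_chrom`` split into 'anc-X' and 'neo-X' at ``breakpoint_bp``
    (``anc_side`` says which side of the breakpoint is ancestral); without a
    breakpoint the whole chromosome is 'anc-X'.  Genes on ``y_chroms`` are
    'Y'; everything else is 'autosome'.
    """
    if anc_side not in ("left", "right"):
        raise ValueError("anc_side must be 'left' or 'right'")
    x_set = {x_chrom} if isinstance(x_chrom, str) else set(x_chrom)
    pos_col = "position" if "position" in genes.columns else "start"
    out = []
    for _, rec in genes.iterrows():
        chrom = rec["chrom"]
        if chrom in y_chroms:
            out.append("Y")
        elif chrom in x_set:
            if breakpoint_bp is None:
                out.append("anc-X")
            else:
                left = rec[pos_col] < breakpoint_bp
                out.append("anc-X" if left == (anc_side == "left") else "neo-X")
        else:
            out.append("autosome")
    return pd.Series(out, index=genes["gene"].to_numpy(), name="stratum")


def select_samples(samples: pd.DataFrame, spec) -> list[str]:
    """Resolve a group spec (sample names, or a {column: value} selector)."""
    if isinstance(spec, Mapping):
        mask = pd.Series(True, index=samples.index)
        for col, val in spec.items():
            mask &= samples[col] == val
        return samples.loc[mask, "sample"].tolist()
    return list(spec)


def filter_expressed(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    group_a,
    group_b,
    min_value: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep genes expressed (group median >= ``min_value``) in either group.

    Group values are medians over the group's samples (replicates).  Returns
    the filtered matrix and kept/dropped counts.
    """
    sa = select_samples(samples, group_a)
    sb = select_samples(samples, group_b)
    if not sa or not sb:
        raise ValueError("both filter groups must contain at least one sample")
    va = matrix[sa].median(axis=1)
    vb = matrix[sb].median(axis=1)
    keep = (va >= min_value) | (vb >= min_value)
    out = matrix.loc[keep]
    return out, {"kept": int(keep.sum()), "dropped": int((~keep).sum())}


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum W of x, p).

    Exact p (full enumeration of rank assignments) when the smaller sample
    has at most 8 observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank-sum of x
    return w, float(res.pvalue)


def hypergeometric_tail(k: int, K: int, n: int, N: int, tail: str = "upper") -> float:
    """P(X >= k) ('upper') or P(X <= k) ('lower') for X ~ Hypergeom(N, K, n).

    N: population size, K: successes in the population, n: draws, k: observed
    successes.
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("inconsistent counts: need 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(n, K)):
        raise ValueError("inconsistent counts: need 0 <= k <= min(n, K)")
    dist = stats.hypergeom(N, K, n)
    return float(dist.sf(k - 1) if tail == "upper" else dist.cdf(k))


def _letter_groups(groups: list, pairs: pd.DataFrame, alpha: float) -> dict:
    """Letters by transitive grouping: connected components of the
    not-significantly-different graph, lettered in group order."""
    parent = {g: g for g in groups}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for _, row in pairs.iterrows():
        if row["p_adj"] >= alpha:
            a, b = find(row["group1"]), find(row["group2"])
            if a != b:
                parent[b] = a
    letters: dict = {}
    names: dict = {}
    for g in groups:
        root = find(g)
        if root not in names:
            names[root] = chr(ord("a") + len(names))
        letters[g] = names[root]
    return letters


@dataclass
class DosageResult:
    """Stratum medians and all pairwise rank tests for one contrast.

    ``summary`` has per-stratum gene counts, median male and female values
    and the median ratio (ratio of medians); ``pairwise`` the Bonferroni-
    corrected Wilcoxon tests over all group pairs; ``letters`` the transitive
    significance groups.
    """

    summary: pd.DataFrame
    pairwise: pd.DataFrame
    letters: dict
    family_size: int
    alpha: float


def dosage_compare(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    partition: pd.Series,
    compartment: str = "soma",
    sexes: Sequence[str] = ("M", "F"),
    alpha: float = 0.05,
) -> DosageResult:
    """Compare expression across chromosome strata and sexes within a compartment.

    Builds one group per (stratum, sex) — the per-gene median over that sex's
    samples in ``compartment`` — then runs every pairwise Wilcoxon rank-sum
    test with Bonferroni correction over the pairs tested and letter groups
    from the non-significant pairs.
    """
    common = matrix.index.intersection(partition.index)
    if len(common) == 0:
        raise ValueError("partition does not cover any gene in the matrix")
    part = partition.loc[common]

    sex_vals: dict[str, pd.Series] = {}
    for sex in sexes:
        cols = select_samples(samples, {"sex": sex, "compartment": compartment})
        if not cols:
            raise ValueError(f"no samples with sex={sex} in compartment={compartment}")
        sex_vals[sex] = matrix.loc[common, cols].median(axis=1)

    strata = [s for s in STRATA_ORDER if s in set(part)] + sorted(
        set(part) - set(STRATA_ORDER)
    )
    groups: list[tuple[str, str]] = []
    data: dict[tuple[str, str], np.ndarray] = {}
    summary_rows = []
    for stratum in strata:
        idx = part.index[part == stratum]
        if len(idx) < 2:
            warnings.warn(f"stratum {stratum!r} has < 2 genes; excluded", stacklevel=2)
            continue
        med = {}
        for sex in sexes:
            vals = sex_vals[sex].loc[idx].to_numpy()
            groups.append((stratum, sex))
            data[(stratum, sex)] = vals
            med[sex] = float(np.median(vals))
        ratio = med["M"] / med["F"] if ("M" in med and "F" in med and med["F"] > 0) else np.nan
        summary_rows.append(
            (stratum, len(idx), med.get("M", np.nan), med.get("F", np.nan), ratio)
        )
    summary = pd.DataFrame(
        summary_rows, columns=["stratum", "n_genes", "median_m", "median_f", "mf_ratio"]
    )

    rows = []
    pairs = list(combinations(groups, 2))
    m = len(pairs)
    for g1, g2 in pairs:
        w, p = wilcoxon_rank_sum(data[g1], data[g2])
        rows.append((g1, g2, w, p, min(1.0, p * m)))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "W", "p", "p_adj"])
    pairwise["significant"] = pairwise["p_adj"] < alpha
    letters = _letter_groups(groups, pairwise, alpha)
    return DosageResult(
        summary=summary, pairwise=pairwise, letters=letters, family_size=m, alpha=alpha
    )


def proto_vs_neo(
    focal_matrix: pd.DataFrame,
    focal_samples: pd.DataFrame,
    outgroup_matrix: pd.DataFrame,
    outgroup_samples: pd.DataFrame,
    ortholog_map: Mapping[str, str],
    neo_genes: Sequence[str],
    compartments: Sequence[str] = ("soma", "gonad"),
    sexes: Sequence[str] = ("M", "F"),
) -> pd.DataFrame:
    """Neo-X expression vs its ancestral (proto-X) level in an outgroup.

    For each sex and compartment, compares focal neo-X gene values with the
    values of their 1:1 orthologs in an outgroup where those genes are still
    autosomal.  A ratio of medians near 1 with a non-significant rank test
    indicates that compensation has restored the ancestral expression level.
    """
    mapped = [(g, ortholog_map[g]) for g in neo_genes if g in ortholog_map]
    mapped = [
        (g, o) for g, o in mapped if g in focal_matrix.index and o in outgroup_matrix.index
    ]
    if len(mapped) < 20:
        warnings.warn(f"only {len(mapped)} mapped neo-X pairs; results may be unstable",
                      stacklevel=2)
    if not mapped:
        raise ValueError("no neo-X genes could be mapped to the outgroup")
    fg = [g for g, _ in mapped]
    og = [o for _, o in mapped]
    rows = []
    for compartment in compartments:
        for sex in sexes:
            fcols = select_samples(focal_samples, {"sex": sex, "compartment": compartment})
            ocols = select_samples(outgroup_samples, {"sex": sex, "compartment": compartment})
            if not fcols or not ocols:
                continue
            fv = focal_matrix.loc[fg, fcols].median(axis=1).to_numpy()
            ov = outgroup_matrix.loc[og, ocols].median(axis=1).to_numpy()
            mf, mo = float(np.median(fv)), float(np.median(ov))
            w, p = wilcoxon_rank_sum(fv, ov)
            rows.append(
                (sex, compartment, len(fv), mf, mo, mf / mo if mo > 0 else np.nan, w, p)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sex", "compartment", "n_pairs",
            "median_neo", "median_proto", "ratio", "W", "p",
        ],
    )


def classify_gonad_bias(
    matrix: pd.DataFrame, samples: pd.DataFrame, fold: float = 2.0
) -> pd.Series:
    """Call each gene ovary-biased, testis-biased, or unbiased.

    Per-tissue values are medians over replicates; a gene is gonad-biased
    when its gonad value is strictly more than ``fold`` times higher than in
    every other assayed tissue.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    tissues = samples["tissue"].unique().tolist()
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    gonads = samples[samples["compartment"] == "gonad"]
    ovary = gonads.loc[gonads["sex"] == "F", "tissue"].unique()
    testis = gonads.loc[gonads["sex"] == "M", "tissue"].unique()
    if len(ovary) != 1 or len(testis) != 1:
        raise ValueError("need exactly one ovary and one testis tissue")
    ovary, testis = ovary[0], testis[0]

    med = pd.DataFrame(
        {
            t: matrix[samples.loc[samples["tissue"] == t, "sample"]].median(axis=1)
            for t in tissues
        }
    )
    ov = med[ovary]
    te = med[testis]
    max_not_ovary = med.drop(columns=[ovary]).max(axis=1)
    max_not_testis = med.drop(columns=[testis]).max(axis=1)
    calls = np.full(len(med), "none", dtype=object)
    calls[(ov > fold * max_not_ovary).to_numpy()] = "ovary"
    calls[(te > fold * max_not_testis).to_numpy()] = "testis"
    return pd.Series(calls, index=med.index, name="bias")


def test_enrichment(
    calls: pd.Series,
    partition: pd.Series,
    alpha: float = 0.05,
    min_genes: int = 20,
    classes: Sequence[str] = ("ovary", "testis"),
    tails: Sequence[str] = ("upper", "lower"),
) -> pd.DataFrame:
    """Hypergeometric enrichment/depletion of biased genes per stratum.

    The background is every gene present in both ``calls`` and
    ``partition``.  Both tails are tested for each stratum x bias class and
    Bonferroni-corrected over all tests; the verdict is 'enriched' or
    'depleted' when the corresponding adjusted p falls below ``alpha``.
    """
    genes = calls.index.intersection(partition.index)
    calls = calls.loc[genes]
    part = partition.loc[genes]
    N = len(genes)
    if N == 0:
        raise ValueError("no genes shared between calls and partition")
    strata = [s for s in STRATA_ORDER if s in set(part)] + sorted(set(part) - set(STRATA_ORDER))
    strata = [s for s in strata if s != "excluded"]
    rows = []
    for stratum in strata:
        in_s = part == stratum
        n = int(in_s.sum())
        if n < min_genes:
            warnings.warn(
                f"stratum {stratum!r} has {n} genes (< {min_genes}); skipped", stacklevel=2
            )
            continue
        for cls in classes:
            K = int((calls == cls).sum())
            k = int(((calls == cls) & in_s).sum())
            p_up = hypergeometric_tail(k, K, n, N, "upper") if "upper" in tails else np.nan
            p_low = hypergeometric_tail(k, K, n, N, "lower") if "lower" in tails else np.nan
            rows.append((stratum, cls, k, n, K, N, p_up, p_low))
    df = pd.DataFrame(
        rows,
        columns=["stratum", "bias_class", "k", "n", "K", "N", "p_enrichment", "p_depletion"],
    )
    m = int(df[["p_enrichment", "p_depletion"]].notna().sum().sum())
    df["p_enrichment_adj"] = np.minimum(1.0, df["p_enrichment"] * m)
    df["p_depletion_adj"] = np.minimum(1.0, df["p_depletion"] * m)
    verdict = np.full(len(df), "ns", dtype=object)
    verdict[(df["p_enrichment_adj"] < alpha).to_numpy(dtype=bool)] = "enriched"
    verdict[(df["p_depletion_adj"] < alpha).to_numpy(dtype=bool)] = "depleted"
    df["verdict"] = verdict
    df.attrs["family_size"] = m
    return df
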