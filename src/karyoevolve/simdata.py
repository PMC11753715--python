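"""Forward simulation of beetle karyotype evolution and the genomic signals it leaves.

The simulator models a set of ancestral linkage groups ("elements"), each a
conserved block of genes, evolving along a rooted species tree by whole-arm
fusions and fissions.  Gene content is conserved: no gains, losses, or
translocations between elements, so every gene carries one immutable element
label.  From a simulated history the module can emit the three observable
layers the inference stages consume:

* cross-species 1:1 ortholog tables with optional within-segment gene
  shuffling (genes never cross a fusion boundary),
* sexed per-window read-depth tracks, where X-linked windows sit at half
  male depth and a neo-X interpolates between autosomal and hemizygous
  depth via the neo-Y homology fraction ``theta``,
* gene-by-tissue expression matrices with configurable dosage compensation
  of hemizygous genes and planted ovary-/testis-biased genes.

All operations are deterministic given their ``seed``.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Fusion",
    "Fission",
    "TipKaryotype",
    "KaryotypeHistory",
    "CoverageSimParams",
    "SimulatedCoverage",
    "Tissue",
    "ExpressionSimParams",
    "SimulatedExpression",
    "default_element_labels",
    "simulate_karyotype_history",
    "simulate_ortholog_table",
    "simulate_coverage",
    "coverage_spec_from_tip",
    "expression_genes_from_tip",
    "simulate_expression",
]

COVERAGE_CLASSES = ("autosome", "ancX", "neoX", "Y")

# A karyotype is a mapping chromosome-id -> list of segments, each segment an
# ordered list of gene ids.  Segment boundaries record fusion joins and
# fission scars; gene shuffling is confined within segments.
Karyotype = dict[str, list[list[str]]]


def default_element_labels(n: int) -> list[str]:
    """Element labels: the sex element 'X' first, then autosomal letters A, B, ...

    The letter X is skipped in the autosomal series; beyond the alphabet the
    labels continue as E25, E26, ...
    """
    if n < 1:
        raise ValueError("need at least one element")
    labels = ["X"]
    i = 0
    while len(labels) < n:
        if i < 26:
            c = chr(ord("A") + i)
            i += 1
            if c == "X":
                continue
            labels.append(c)
        else:
            labels.append(f"E{i}")
            i += 1
    return labels


@dataclass(frozen=True)
class Fusion:
    """End-to-end joining of two chromosomes, each in a uniform orientation."""

    left: str
    right: str
    flip_left: bool
    flip_right: bool
    result: str

    kind = "fusion"


@dataclass(frozen=True)
class Fission:
    """Split of a chromosome at a gene boundary; ``breakpoint`` genes stay left."""

    chrom: str
    breakpoint: int
    left_result: str
    right_result: str

    kind = "fission"


def _flip(segments: list[list[str]]) -> list[list[str]]:
    return [seg[::-1] for seg in segments[::-1]]


def _gene_count(segments: list[list[str]]) -> int:
    return sum(len(s) for s in segments)


def _apply_event(kar: Karyotype, ev: Union[Fusion, Fission]) -> None:
    if isinstance(ev, Fusion):
        left = kar.pop(ev.left)
        right = kar.pop(ev.right)
        if ev.flip_left:
            left = _flip(left)
        if ev.flip_right:
            right = _flip(right)
        kar[ev.result] = left + right
    else:
        segments = kar.pop(ev.chrom)
        n = _gene_count(segments)
        if not (0 < ev.breakpoint < n):
            raise ValueError(f"fission breakpoint {ev.breakpoint} outside (0, {n})")
        left: list[list[str]] = []
        right: list[list[str]] = []
        seen = 0
        for seg in segments:
            if seen >= ev.breakpoint:
                right.append(seg)
            elif seen + len(seg) <= ev.breakpoint:
                left.append(seg)
            else:
                cut = ev.breakpoint - seen
                left.append(seg[:cut])
                right.append(seg[cut:])
            seen += len(seg)
        kar[ev.left_result] = left
        kar[ev.right_result] = right


@dataclass
class TipKaryotype:
    """Final chromosome complement of one tip, with segment structure retained.

    Chromosomes are renamed ``chr1..chrK`` ordered by decreasing gene count
    (ties broken by smallest gene id) so tip naming is assembly-like and
    deterministic.
    """

    name: str
    segments: dict[str, list[list[str]]]
    gene_element: Mapping[str, str]

    def chromosomes(self) -> list[str]:
        return sorted(self.segments, key=_natural_key)

    def genes(self, chrom: str) -> list[str]:
        return [g for seg in self.segments[chrom] for g in seg]

    def gene_count(self) -> int:
        return sum(_gene_count(s) for s in self.segments.values())

    def gene_positions(self) -> dict[str, tuple[str, int]]:
        """gene id -> (chromosome, ordinal position along the chromosome)."""
        out: dict[str, tuple[str, int]] = {}
        for chrom in self.chromosomes():
            for i, g in enumerate(self.genes(chrom)):
                out[g] = (chrom, i)
        return out

    def element_content(self, chrom: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.genes(chrom):
            el = self.gene_element[g]
            counts[el] = counts.get(el, 0) + 1
        return counts

    def chroms_with_element(self, element: str) -> list[str]:
        return [c for c in self.chromosomes() if element in self.element_content(c)]


def _natural_key(s: str):
    return tuple(int(t) if t.isdigit() else t for t in re.split(r"(\d+)", str(s)))


def _relabel_tip(kar: Karyotype) -> dict[str, list[list[str]]]:
    order = sorted(kar, key=lambda c: (-_gene_count(kar[c]), min(g for seg in kar[c] for g in seg)))
    return {f"chr{i + 1}": copy.deepcopy(kar[c]) for i, c in enumerate(order)}


@dataclass
class KaryotypeHistory:
    """A replayable record of karyotype evolution along a species tree."""

    tree: dendropy.Tree
    elements: list[str]
    genes_per_element: int
    gene_element: dict[str, str]
    ancestral: Karyotype
    events: dict[str, list[Union[Fusion, Fission]]]
    tips: dict[str, TipKaryotype]
    skipped: list[str] = field(default_factory=list)

    def node_key(self, node: dendropy.Node) -> str:
        return node.taxon.label if node.taxon is not None else node.label

    def lineage_events(self, tip_name: str) -> list[Union[Fusion, Fission]]:
        """Events applied on the root-to-tip path, in replay order."""
        leaf = None
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == tip_name:
                leaf = lf
                break
        if leaf is None:
            raise KeyError(tip_name)
        path: list[dendropy.Node] = []
        node = leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        out: list[Union[Fusion, Fission]] = []
        for nd in reversed(path):
            out.extend(self.events.get(self.node_key(nd), []))
        return out

    def lineage_event_counts(self, tip_name: str) -> tuple[int, int]:
        evs = self.lineage_events(tip_name)
        return (sum(isinstance(e, Fusion) for e in evs), sum(isinstance(e, Fission) for e in evs))

    def replay(self, tip_name: str) -> dict[str, list[list[str]]]:
        """Re-derive a tip chromosome map by replaying recorded events from the root."""
        kar = copy.deepcopy(self.ancestral)
        for ev in self.lineage_events(tip_name):
            _apply_event(kar, ev)
        return _relabel_tip(kar)

    def verify_replay(self) -> bool:
        return all(self.replay(t) == self.tips[t].segments for t in self.tips)

    def composition(self, tip_name: str, min_genes: int = 0) -> dict[str, list[tuple[str, int]]]:
        """Ground-truth element composition: element -> [(tip chromosome, n genes)]."""
        tip = self.tips[tip_name]
        out: dict[str, list[tuple[str, int]]] = {el: [] for el in self.elements}
        for chrom in tip.chromosomes():
            for el, k in tip.element_content(chrom).items():
                if k >= min_genes:
                    out[el].append((chrom, k))
        for el in out:
            out[el].sort(key=lambda ck: (-ck[1], _natural_key(ck[0])))
        return out

    def parsimony_event_counts(self, tip_name: str, min_genes: int = 0) -> tuple[int, int]:
        """Star-parsimony fusion/fission counts implied by the tip composition.

        Fissions: one per extra chromosome carrying an element; fusions: one
        per extra element sharing a chromosome.  Equals the simulated counts
        whenever the lineage's events do not cancel.
        """
        comp = self.composition(tip_name, min_genes=min_genes)
        fissions = sum(max(0, len(cells) - 1) for cells in comp.values())
        per_chrom: dict[str, int] = {}
        for cells in comp.values():
            for chrom, _ in cells:
                per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
        fusions = sum(max(0, k - 1) for k in per_chrom.values())
        return fusions, fissions

    def truth_table(self) -> pd.DataFrame:
        """Per-gene truth: species placements plus the element label."""
        rows = []
        for tip_name in sorted(self.tips):
            pos = self.tips[tip_name].gene_positions()
            for g, (chrom, p) in pos.items():
                rows.append((g, tip_name, chrom, p, self.gene_element[g]))
        df = pd.DataFrame(rows, columns=["gene_id", "species", "chrom", "position", "element"])
        return df.sort_values(["gene_id", "species"], kind="stable").reset_index(drop=True)


def _parse_tree(tree: Union[str, dendropy.Tree]) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    try:
        return dendropy.Tree.get(data=tree, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick tree: {exc}") from exc


def simulate_karyotype_history(
    tree: Union[str, dendropy.Tree],
    n_elements: int = 9,
    genes_per_element: int = 200,
    fusion_rate: float = 0.0,
    fission_rate: float = 0.0,
    seed: int = 0,
    *,
    max_fusions_per_branch: int | None = None,
    max_fissions_per_branch: int | None = None,
    element_labels: Sequence[str] | None = None,
) -> KaryotypeHistory:
    """Evolve an ancestral karyotype of ``n_elements`` chromosomes along a tree.

    Per-branch fusion and fission counts are Poisson with mean
    ``rate x branch length`` (optionally capped); fusions join two uniformly
    chosen chromosomes end-to-end with uniform orientations, fissions split a
    uniformly chosen multi-gene chromosome at a uniform internal gene
    boundary.  A fission requested when every chromosome holds a single gene
    is skipped and logged, not fatal.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    if genes_per_element < 1:
        raise ValueError("genes_per_element must be >= 1")
    if fusion_rate < 0 or fission_rate < 0:
        raise ValueError("event rates must be >= 0")
    t = _parse_tree(tree)
    leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least two tips")
    if len(set(leaves)) != len(leaves):
        raise ValueError("tip names must be unique")
    labels = list(element_labels) if element_labels is not None else default_element_labels(n_elements)
    if len(labels) != n_elements or len(set(labels)) != n_elements:
        raise ValueError("element_labels must be unique and match n_elements")

    width = max(4, len(str(genes_per_element)))
    ancestral: Karyotype = {
        lab: [[f"{lab}g{j:0{width}d}" for j in range(genes_per_element)]] for lab in labels
    }
    gene_element = {g: lab for lab in labels for g in ancestral[lab][0]}

    # name internal nodes so the event log has stable keys
    idx = 0
    for node in t.preorder_node_iter():
        if node.taxon is None and not node.label:
            node.label = f"nd{idx}"
            idx += 1

    rng = np.random.default_rng(seed)
    counter = 0
    events: dict[str, list[Union[Fusion, Fission]]] = {}
    tips: dict[str, TipKaryotype] = {}
    skipped: list[str] = []
    kar_at: dict[dendropy.Node, Karyotype] = {}

    for node in t.preorder_node_iter():
        if node.parent_node is None:
            kar_at[node] = copy.deepcopy(ancestral)
            events[node.taxon.label if node.taxon else node.label] = []
            continue
        length = node.edge.length
        if length is None:
            length = 0.0
        if length < 0:
            raise ValueError("branch lengths must be non-negative")
        kar = copy.deepcopy(kar_at[node.parent_node])
        key = node.taxon.label if node.taxon is not None else node.label
        n_fus = int(rng.poisson(fusion_rate * length))
        n_fis = int(rng.poisson(fission_rate * length))
        if max_fusions_per_branch is not None:
            n_fus = min(n_fus, max_fusions_per_branch)
        if max_fissions_per_branch is not None:
            n_fis = min(n_fis, max_fissions_per_branch)
        kinds = ["fusion"] * n_fus + ["fission"] * n_fis
        rng.shuffle(kinds)
        applied: list[Union[Fusion, Fission]] = []
        for kind in kinds:
            if kind == "fusion":
                if len(kar) < 2:
                    skipped.append(f"{key}: fusion skipped, single chromosome left")
                    continue
                ids = sorted(kar, key=_natural_key)
                i, j = rng.choice(len(ids), size=2, replace=False)
                flips = rng.random(2) < 0.5
                counter += 1
                ev: Union[Fusion, Fission] = Fusion(
                    ids[int(i)], ids[int(j)], bool(flips[0]), bool(flips[1]), f"fu{counter}"
                )
            else:
                eligible = sorted((c for c in kar if _gene_count(kar[c]) >= 2), key=_natural_key)
                if not eligible:
                    skipped.append(f"{key}: fission skipped, all chromosomes single-gene")
                    continue
                c = eligible[int(rng.integers(len(eligible)))]
                bp = int(rng.integers(1, _gene_count(kar[c])))
                counter += 1
                ev = Fission(c, bp, f"fi{counter}a", f"fi{counter}b")
            _apply_event(kar, ev)
            applied.append(ev)
        events[key] = applied
        kar_at[node] = kar
        if node.is_leaf():
            tips[key] = TipKaryotype(key, _relabel_tip(kar), gene_element)

    return KaryotypeHistory(
        tree=t,
        elements=labels,
        genes_per_element=genes_per_element,
        gene_element=gene_element,
        ancestral=ancestral,
        events=events,
        tips=tips,
        skipped=skipped,
    )


def simulate_ortholog_table(
    history: KaryotypeHistory, shuffle_rate: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Emit a strictly 1:1 ortholog table from a simulated history.

    Every gene appears once per tip with its chromosome and ordinal position.
    With probability ``shuffle_rate`` a gene's position is re-drawn uniformly
    within its segment (shuffled genes trade places), so gene order is
    scrambled within ancestral blocks but never across a fusion boundary.

    Columns are ``{species}:chrom`` and ``{species}:pos``; the index is
    ``ortholog_id``.
    """
    if not 0.0 <= shuffle_rate <= 1.0:
        raise ValueError("shuffle_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(history.gene_element)
    data: dict[str, pd.Series] = {}
    for tip_name in sorted(history.tips):
        tip = history.tips[tip_name]
        chrom_of: dict[str, str] = {}
        pos_of: dict[str, int] = {}
        for chrom in tip.chromosomes():
            offset = 0
            for seg in tip.segments[chrom]:
                n = len(seg)
                pos = np.arange(n)
                sel = np.flatnonzero(rng.random(n) < shuffle_rate)
                if sel.size > 1:
                    pos[sel] = rng.permutation(sel)
                for i, g in enumerate(seg):
                    chrom_of[g] = chrom
                    pos_of[g] = offset + int(pos[i])
                offset += n
        data[f"{tip_name}:chrom"] = pd.Series(chrom_of)
        data[f"{tip_name}:pos"] = pd.Series(pos_of)
    table = pd.DataFrame(data).loc[genes]
    table.index.name = "ortholog_id"
    return table


@dataclass
class CoverageSimParams:
    """Negative-binomial read-depth model for sexed samples.

    ``theta`` is the neo-Y homology fraction: the share of ancestral male
    depth a neo-X window still attracts from its not-yet-degenerate neo-Y
    partner.  theta=1 makes the neo-X indistinguishable from autosomes in
    males; theta=0 makes it fully hemizygous.  Y windows receive a small
    noise-floor female depth (default 1% of the female autosomal mean) to
    emulate repetitive cross-mapping.
    """

    window_size: int = 50_000
    mean_depth_f: float = 20.0
    mean_depth_m: float = 30.0
    dispersion: float = 10.0
    theta: float = 0.0
    y_noise_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.mean_depth_f <= 0 or self.mean_depth_m <= 0:
            raise ValueError("mean depths must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.y_noise_frac < 0:
            raise ValueError("y_noise_frac must be >= 0")

    def class_means(self) -> dict[str, tuple[float, float]]:
        """Expected (female, male) per-window depth for each chromosome class."""
        df_, dm = self.mean_depth_f, self.mean_depth_m
        return {
            "autosome": (df_, dm),
            "ancX": (df_, dm / 2.0),
            "neoX": (df_, dm * (1.0 + self.theta) / 2.0),
            "Y": (df_ * self.y_noise_frac, dm / 2.0),
        }


@dataclass
class SimulatedCoverage:
    female: pd.DataFrame
    male: pd.DataFrame
    truth: pd.DataFrame  # chrom, start, end, class

    def chrom_sizes(self) -> dict[str, int]:
        return self.female.groupby("chrom", sort=True)["end"].max().to_dict()


ChromSpec = Mapping[str, Union[tuple[str, int], Sequence[tuple[str, int]]]]


def _normalize_spec(chrom_spec: ChromSpec) -> dict[str, list[tuple[str, int]]]:
    out: dict[str, list[tuple[str, int]]] = {}
    for chrom, spec in chrom_spec.items():
        if isinstance(spec, tuple) and len(spec) == 2 and isinstance(spec[0], str):
            spec = [spec]
        runs = []
        for cls, n in spec:
            if cls not in COVERAGE_CLASSES:
                raise ValueError(f"unknown coverage class {cls!r} for {chrom}")
            if n < 1:
                raise ValueError(f"segment of {chrom} must span >= 1 window")
            runs.append((cls, int(n)))
        out[chrom] = runs
    return out


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(float)


def simulate_coverage(chrom_spec: ChromSpec, params: CoverageSimParams) -> SimulatedCoverage:
    """Simulate female and male window-depth tracks over the given chromosomes.

    ``chrom_spec`` maps chromosome id to a (class, n_windows) run or a list of
    runs; a list models a fused chromosome whose segments differ in class
    (e.g. anc-X followed by neo-X).
    """
    spec = _normalize_spec(chrom_spec)
    means = params.class_means()
    rng = np.random.default_rng(params.seed)
    rows_f, rows_m, rows_t = [], [], []
    for chrom in sorted(spec, key=_natural_key):
        start = 0
        for cls, n in spec[chrom]:
            mf, mm = means[cls]
            depths_f = _nb_draw(rng, mf, params.dispersion, n)
            depths_m = _nb_draw(rng, mm, params.dispersion, n)
            for i in range(n):
                s = start + i * params.window_size
                e = s + params.window_size
                rows_f.append((chrom, s, e, depths_f[i]))
                rows_m.append((chrom, s, e, depths_m[i]))
                rows_t.append((chrom, s, e, cls))
            start += n * params.window_size
    cols = ["chrom", "start", "end", "depth"]
    return SimulatedCoverage(
        female=pd.DataFrame(rows_f, columns=cols),
        male=pd.DataFrame(rows_m, columns=cols),
        truth=pd.DataFrame(rows_t, columns=["chrom", "start", "end", "class"]),
    )


def coverage_spec_from_tip(
    tip: TipKaryotype,
    x_element: str = "X",
    genes_per_window: int = 4,
) -> dict[str, list[tuple[str, int]]]:
    """Derive a coverage chromosome spec from a simulated tip karyotype.

    Genes of the sex element become anc-X windows; genes sharing a chromosome
    with the sex element but belonging to another element become neo-X
    windows; all other chromosomes are autosomal.  Window counts are scaled
    from gene counts at ``genes_per_window``.
    """
    if genes_per_window < 1:
        raise ValueError("genes_per_window must be >= 1")
    spec: dict[str, list[tuple[str, int]]] = {}
    for chrom in tip.chromosomes():
        content = tip.element_content(chrom)
        if x_element not in content:
            n = max(1, -(-_gene_count(tip.segments[chrom]) // genes_per_window))
            spec[chrom] = [("autosome", n)]
            continue
        # runs of anc-X vs neo-X along the gene order
        runs: list[tuple[str, int]] = []
        for g in tip.genes(chrom):
            cls = "ancX" if tip.gene_element[g] == x_element else "neoX"
            if runs and runs[-1][0] == cls:
                runs[-1] = (cls, runs[-1][1] + 1)
            else:
                runs.append((cls, 1))
        spec[chrom] = [(cls, max(1, -(-k // genes_per_window))) for cls, k in runs]
    return spec


@dataclass(frozen=True)
class Tissue:
    label: str
    sex: str  # 'M' or 'F'
    compartment: str  # 'gonad' or 'soma'
    n_replicates: int = 2


def default_tissues() -> list[Tissue]:
    return [
        Tissue("head_m", "M", "soma"),
        Tissue("head_f", "F", "soma"),
        Tissue("testis", "M", "gonad"),
        Tissue("ovary", "F", "gonad"),
    ]


@dataclass
class ExpressionSimParams:
    """Log-normal FPKM model with dosage compensation and gonad-biased genes.

    ``dc_mode`` sets the male expression factor applied to hemizygous
    (X-stratum) genes: 'complete' -> 1 (expected M/F ratio 1), 'none' -> 0.5,
    'partial' -> (1 + dc_lambda)/2.  Gonad-biased genes are planted at the
    given per-stratum fractions and multiplied by ``bias_fold`` in their
    target gonad tissue only.
    """

    tissues: list[Tissue] = field(default_factory=default_tissues)
    log_mean: float = 3.0
    gene_log_sd: float = 1.0
    noise_log_sd: float = 0.2
    dc_mode: str = "complete"
    dc_lambda: float | None = None
    frac_ovary_biased: Union[float, Mapping[str, float]] = 0.10
    frac_testis_biased: Union[float, Mapping[str, float]] = 0.10
    bias_fold: float = 4.0
    hemizygous_strata: tuple[str, ...] = ("anc-X", "neo-X")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissues:
            raise ValueError("tissue list must not be empty")
        sexes = {t.sex for t in self.tissues}
        if not {"M", "F"} <= sexes:
            raise ValueError("need at least one male and one female tissue")
        if self.dc_mode not in ("complete", "none", "partial"):
            raise ValueError("dc_mode must be complete, none, or partial")
        if self.dc_mode == "partial":
            if self.dc_lambda is None or not 0.0 <= self.dc_lambda <= 1.0:
                raise ValueError("partial dc requires dc_lambda in [0, 1]")
        if self.bias_fold <= 1:
            raise ValueError("bias_fold must exceed 1")
        if self.noise_log_sd < 0 or self.gene_log_sd < 0:
            raise ValueError("log-sd parameters must be >= 0")

    def dc_factor(self) -> float:
        if self.dc_mode == "complete":
            return 1.0
        if self.dc_mode == "none":
            return 0.5
        return (1.0 + float(self.dc_lambda)) / 2.0

    def _frac(self, value: Union[float, Mapping[str, float]], stratum: str) -> float:
        f = value.get(stratum, 0.0) if isinstance(value, Mapping) else float(value)
        if not 0.0 <= f <= 1.0:
            raise ValueError("bias fractions must be in [0, 1]")
        return f

    def bias_fracs(self, stratum: str) -> tuple[float, float]:
        fo = self._frac(self.frac_ovary_biased, stratum)
        ft = self._frac(self.frac_testis_biased, stratum)
        if fo + ft > 1.0:
            raise ValueError(f"bias fractions for stratum {stratum} sum above 1")
        return fo, ft


@dataclass
class SimulatedExpression:
    matrix: pd.DataFrame  # gene x sample
    samples: pd.DataFrame  # sample, tissue, sex, compartment, replicate
    truth: pd.DataFrame  # gene, stratum, bias


def expression_genes_from_tip(tip: TipKaryotype, x_element: str = "X") -> pd.DataFrame:
    """Gene table with sex-linkage strata ('anc-X', 'neo-X', 'autosome') for a tip."""
    rows = []
    for chrom in tip.chromosomes():
        has_x = x_element in tip.element_content(chrom)
        for pos, g in enumerate(tip.genes(chrom)):
            if tip.gene_element[g] == x_element:
                stratum = "anc-X"
            elif has_x:
                stratum = "neo-X"
            else:
                stratum = "autosome"
            rows.append((g, chrom, pos, stratum))
    return pd.DataFrame(rows, columns=["gene", "chrom", "position", "stratum"])


def simulate_expression(genes: pd.DataFrame, params: ExpressionSimParams) -> SimulatedExpression:
    """Simulate an FPKM-like matrix for ``genes`` (columns: gene, stratum).

    Returns the matrix, the sample sheet, and per-gene truth labels
    (stratum and planted gonad bias) for recall/precision testing.
    """
    if "gene" not in genes.columns or "stratum" not in genes.columns:
        raise ValueError("genes frame needs 'gene' and 'stratum' columns")
    rng = np.random.default_rng(params.seed)
    gene_ids = genes["gene"].to_numpy()
    strata = genes["stratum"].to_numpy()
    n = len(gene_ids)
    base = np.exp(params.log_mean + rng.normal(0.0, params.gene_log_sd, n))

    u = rng.random(n)
    bias = np.full(n, "none", dtype=object)
    for stratum in pd.unique(strata):
        fo, ft = params.bias_fracs(stratum)
        mask = strata == stratum
        bias[mask & (u < fo)] = "ovary"
        bias[mask & (u >= fo) & (u < fo + ft)] = "testis"

    hemi = np.isin(strata, params.hemizygous_strata)
    dc = params.dc_factor()

    cols: dict[str, np.ndarray] = {}
    sample_rows = []
    for tissue in params.tissues:
        target = "ovary" if tissue.sex == "F" else "testis"
        for rep in range(1, tissue.n_replicates + 1):
            vals = base * np.exp(rng.normal(0.0, params.noise_log_sd, n))
            if tissue.sex == "M":
                vals = np.where(hemi, vals * dc, vals)
            if tissue.compartment == "gonad":
                vals = np.where(bias == target, vals * params.bias_fold, vals)
            name = f"{tissue.label}_r{rep}"
            cols[name] = vals
            sample_rows.append((name, tissue.label, tissue.sex, tissue.compartment, rep))

    matrix = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "tissue", "sex", "compartment", "replicate"]
    )
    truth = pd.DataFrame({"gene": gene_ids, "stratum": strata, "bias": bias})
    return SimulatedExpression(matrix=matrix, samples=samples, truth=truth)
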