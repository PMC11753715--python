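"""Ancestral linkage-group assignment from 1:1 ortholog tables.

Beetle chromosomes descend from a small set of conserved ancestral linkage
groups whose gene content survives hundreds of millions of years of fusions
and fissions.  Anchoring on one focal species' linkage groups, this module
counts shared orthologs between focal and target chromosomes, promotes a
focal linkage group to an ancestral element when a majority of its placed
orthologs land on a single chromosome in at least one target species,
tabulates the element-by-species composition (how many chromosomes carry
each element, and which), counts the fusion and fission events implied
relative to a one-element-one-chromosome ancestor, and identifies which
elements are sex-linked — splitting ancestral-X from autosome-derived
(neo-X) components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .simdata import _natural_key

__all__ = [
    "HomologyMatrix",
    "ElementAssignment",
    "EventCount",
    "species_in_table",
    "build_homology_matrix",
    "assign_elements",
    "composition_table",
    "count_events",
    "conserved_sex_orthologs",
    "detect_neo_sex_elements",
]


def species_in_table(table: pd.DataFrame) -> list[str]:
    """Species present in an ortholog table (columns '{sp}:chrom'/'{sp}:pos')."""
    return sorted({c.rsplit(":", 1)[0] for c in table.columns if c.endswith(":chrom")})


def _chrom_col(table: pd.DataFrame, species: str) -> pd.Series:
    col = f"{species}:chrom"
    if col not in table.columns:
        raise ValueError(f"species {species!r} absent from ortholog table")
    return table[col]


@dataclass
class HomologyMatrix:
    """Shared-ortholog counts: focal chromosome x target chromosome."""

    counts: pd.DataFrame
    focal: str
    target: str
    n_placed: int
    n_dropped: int

    def margin_focal(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def margin_target(self) -> pd.Series:
        return self.counts.sum(axis=0)


def build_homology_matrix(table: pd.DataFrame, focal: str, target: str) -> HomologyMatrix:
    """Count 1:1 orthologs per (focal chromosome, target chromosome) pair.

    Rows missing a placement in either species are dropped and counted.
    """
    fc = _chrom_col(table, focal)
    tc = _chrom_col(table, target)
    placed = fc.notna() & tc.notna()
    n_dropped = int((~placed).sum())
    sub = pd.DataFrame({"focal": fc[placed], "target": tc[placed]})
    if len(sub) == 0:
        warnings.warn(f"no orthologs placed in both {focal} and {target}", stacklevel=2)
        counts = pd.DataFrame(dtype=int)
    else:
        counts = pd.crosstab(sub["focal"], sub["target"])
        counts = counts.loc[
            sorted(counts.index, key=_natural_key), sorted(counts.columns, key=_natural_key)
        ]
    counts.index.name = focal
    counts.columns.name = target
    return HomologyMatrix(
        counts=counts, focal=focal, target=target, n_placed=int(len(sub)), n_dropped=n_dropped
    )


@dataclass
class ElementAssignment:
    """Mapping of focal linkage groups to ancestral elements.

    ``labels`` maps each focal linkage group to its element label ('X' for
    the focal sex chromosome, 'A', 'B', ... for autosomal elements, '-' when
    unassigned).  ``cells`` holds, per (focal LG, target species), the target
    chromosomes carrying at least ``min_orthologs`` of the group, with
    counts — the "k(chrom, ...)" cells of the composition table.
    """

    focal: str
    targets: list[str]
    lgs: list[str]
    labels: dict[str, str]
    cells: dict[str, dict[str, list[tuple[str, int]]]]
    min_orthologs: int
    majority_frac: float
    matrices: dict[str, HomologyMatrix] = field(default_factory=dict, repr=False)

    def assigned_lgs(self) -> list[str]:
        return [lg for lg in self.lgs if self.labels[lg] != "-"]

    def lg_of_label(self, label: str) -> str:
        for lg, lab in self.labels.items():
            if lab == label:
                return lg
        raise KeyError(label)

    def gene_elements(self, table: pd.DataFrame) -> pd.Series:
        """Element label for every ortholog, via its focal-species chromosome."""
        fc = _chrom_col(table, self.focal)
        return fc.map(lambda c: self.labels.get(c, "-")).rename("element")


def assign_elements(
    matrices: dict[str, HomologyMatrix],
    min_orthologs: int = 20,
    majority_frac: float = 0.5,
    focal_x: str | None = None,
) -> ElementAssignment:
    """Promote focal linkage groups to ancestral elements by the majority rule.

    A focal LG becomes an element iff, in at least one target species,
    strictly more than ``majority_frac`` of its placed orthologs (and at
    least ``min_orthologs`` of them) fall on a single target chromosome;
    a tie at exactly the majority fraction is conservatively unassigned.
    ``focal_x`` names the focal sex chromosome, labelled 'X' first; remaining
    elements are lettered A, B, ... in focal LG order.
    """
    if not matrices:
        raise ValueError("need at least one target species")
    if not 0.0 < majority_frac < 1.0:
        raise ValueError("majority_frac must be in (0, 1)")
    focals = {m.focal for m in matrices.values()}
    if len(focals) != 1:
        raise ValueError(f"matrices disagree on the focal species: {sorted(focals)}")
    focal = focals.pop()
    targets = sorted(matrices)
    lgs = sorted({lg for m in matrices.values() for lg in m.counts.index}, key=_natural_key)

    assigned: dict[str, bool] = {}
    cells: dict[str, dict[str, list[tuple[str, int]]]] = {}
    for lg in lgs:
        ok = False
        per_target: dict[str, list[tuple[str, int]]] = {}
        for sp in targets:
            counts = matrices[sp].counts
            if lg in counts.index:
                row = counts.loc[lg]
                top = int(row.max()) if len(row) else 0
                tot = int(row.sum())
                if tot > 0 and top >= min_orthologs and top > majority_frac * tot:
                    ok = True
                kept = [
                    (chrom, int(row[chrom]))
                    for chrom in row.index
                    if row[chrom] >= min_orthologs
                ]
                kept.sort(key=lambda ck: (-ck[1], _natural_key(ck[0])))
                per_target[sp] = kept
            else:
                per_target[sp] = []
        assigned[lg] = ok
        cells[lg] = per_target

    labels: dict[str, str] = {lg: "-" for lg in lgs}
    letters = iter(c for c in "ABCDEFGHIJKLMNOPQRSTUVWYZ")  # X reserved
    ordered = [lg for lg in lgs if assigned[lg]]
    if focal_x is not None and focal_x in labels and assigned.get(focal_x, False):
        labels[focal_x] = "X"
        ordered = [lg for lg in ordered if lg != focal_x]
    for lg in ordered:
        labels[lg] = next(letters)

    return ElementAssignment(
        focal=focal,
        targets=targets,
        lgs=lgs,
        labels=labels,
        cells=cells,
        min_orthologs=min_orthologs,
        majority_frac=majority_frac,
        matrices=dict(matrices),
    )


def _cell_string(cell: list[tuple[str, int]]) -> str:
    if not cell:
        return "0"
    return f"{len(cell)}({','.join(str(c) for c, _ in cell)})"


def composition_table(assignment: ElementAssignment) -> pd.DataFrame:
    """Element x species composition, mirroring the 'k(chrom, ...)' cell style.

    Rows are ordered X first, then lettered elements, with unassigned focal
    linkage groups last as dash rows of zeros.
    """
    if not assignment.lgs:
        raise ValueError("empty assignment")

    def _row_key(lg: str):
        lab = assignment.labels[lg]
        return (0 if lab == "X" else 1 if lab != "-" else 2, lab, _natural_key(lg))

    rows = []
    for lg in sorted(assignment.lgs, key=_row_key):
        rec = {"focal_lg": lg, "element": assignment.labels[lg]}
        for sp in assignment.targets:
            rec[sp] = _cell_string(assignment.cells[lg][sp])
        rows.append(rec)
    return pd.DataFrame(rows).set_index("focal_lg")


@dataclass
class EventCount:
    """Fusions and fissions implied for one species vs the element ancestor."""

    species: str
    n_fusions: int
    n_fissions: int


def count_events(assignment: ElementAssignment, species: str) -> EventCount:
    """Star-parsimony event counts relative to one-element-one-chromosome.

    Fissions: each extra chromosome carrying an element; fusions: each extra
    element sharing a chromosome.  Only assigned elements and cells at or
    above ``min_orthologs`` contribute.
    """
    if species not in assignment.targets:
        raise ValueError(f"assignment does not cover species {species!r}")
    fissions = 0
    per_chrom: dict[str, set[str]] = {}
    for lg in assignment.assigned_lgs():
        cell = assignment.cells[lg][species]
        if cell:
            fissions += len(cell) - 1
        for chrom, _ in cell:
            per_chrom.setdefault(chrom, set()).add(assignment.labels[lg])
    fusions = sum(len(els) - 1 for els in per_chrom.values())
    return EventCount(species=species, n_fusions=fusions, n_fissions=fissions)


def _x_chrom_set(sex_calls) -> set[str]:
    """Accept a classify_scaffolds frame or a plain collection of X scaffolds."""
    if isinstance(sex_calls, pd.DataFrame):
        return set(sex_calls.loc[sex_calls["call"] == "X_linked", "scaffold"])
    return set(sex_calls)


def conserved_sex_orthologs(table: pd.DataFrame, sex_calls: dict[str, object]) -> set[str]:
    """Orthologs X-linked in every listed species.

    ``sex_calls`` maps species to either a scaffold-call frame from
    ``covsex.classify_scaffolds`` or a set of X-linked chromosome ids.
    """
    if len(sex_calls) < 2:
        raise ValueError("need X calls for at least two species")
    mask = pd.Series(True, index=table.index)
    for sp, calls in sex_calls.items():
        chroms = _x_chrom_set(calls)
        mask &= _chrom_col(table, sp).isin(chroms)
    return set(table.index[mask])


def detect_neo_sex_elements(
    assignment: ElementAssignment,
    sex_calls,
    species: str,
    min_orthologs: int | None = None,
) -> pd.DataFrame:
    """Which elements are sex-linked in one species, anc-X vs neo split.

    Sums, per element, the orthologs landing on the species' X-called
    scaffolds; elements reaching ``min_orthologs`` are reported, with the
    focal sex element flagged 'ancestral-X' and all others 'neo'.
    """
    if species not in assignment.matrices:
        raise ValueError(f"no homology matrix stored for species {species!r}")
    if min_orthologs is None:
        min_orthologs = assignment.min_orthologs
    x_chroms = _x_chrom_set(sex_calls)
    counts = assignment.matrices[species].counts
    x_cols = [c for c in counts.columns if c in x_chroms]
    rows = []
    for lg in assignment.assigned_lgs():
        n_x = int(counts.loc[lg, x_cols].sum()) if (lg in counts.index and x_cols) else 0
        if n_x >= min_orthologs:
            label = assignment.labels[lg]
            rows.append((label, lg, n_x, "ancestral-X" if label == "X" else "neo"))
    df = pd.DataFrame(rows, columns=["element", "focal_lg", "n_x_orthologs", "kind"])
    return df.sort_values(["kind", "element"], kind="stable").reset_index(drop=True)
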