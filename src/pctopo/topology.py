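"""Residue contact maps and circuit-topology relations.

Circuit topology classifies every pair of chain contacts by how their
sequence intervals relate: series (S, disjoint), parallel (P, one interval
nested strictly inside the other; the inner contact is "in parallel" with
the outer, the outer is "in inverse parallel", P⁻¹, with the inner), and
cross (X, partial overlap). Pairs sharing an endpoint are labelled
"concerted" and kept out of the four basic counts by default.

The per-residue statistic used by the responsiveness decision tree is the
*local* circuit topology: for each relation type, the number of distinct
contacts elsewhere in the map standing in that relation to at least one
contact formed by the residue. A residue sitting on inner (early-forming)
contacts of nested pairs accumulates a high inverse-parallel count — the
signature of early-folding positions.

Two contact-definition presets are provided, reflecting the two published
parameterisations: ``"methods"`` (≥5 atom pairs of any type within 4.5 Å)
and ``"results"`` (≥6 heavy-atom pairs within 8 Å). Neither is privileged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from pctopo.structure import Structure

SERIES = "S"
PARALLEL = "P"
INVERSE_PARALLEL = "P-1"
CROSS = "X"
CONCERTED = "concerted"

RELATIONS = (SERIES, PARALLEL, INVERSE_PARALLEL, CROSS)


@dataclass(frozen=True)
class ContactParams:
    """Thresholds defining a residue-residue contact."""

    atom_dist_cutoff: float = 4.5  # Å, inclusive
    min_atom_pairs: int = 5
    min_seq_sep: int = 2
    heavy_only: bool = True

    def __post_init__(self):
        if self.atom_dist_cutoff <= 0:
            raise ValueError("atom_dist_cutoff must be positive")
        if self.min_atom_pairs < 1:
            raise ValueError("min_atom_pairs must be >= 1")
        if self.min_seq_sep < 1:
            raise ValueError("min_seq_sep must be >= 1")


#: named presets for the two published contact definitions
PRESETS: dict[str, ContactParams] = {
    "methods": ContactParams(atom_dist_cutoff=4.5, min_atom_pairs=5, min_seq_sep=2, heavy_only=False),
    "results": ContactParams(atom_dist_cutoff=8.0, min_atom_pairs=6, min_seq_sep=2, heavy_only=True),
}


@dataclass(frozen=True, order=True)
class Contact:
    """A contact between sequence positions i < j; its interval is [i, j]."""

    i: int
    j: int
    n_atom_pairs: int = 1

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError(f"contact requires i < j, got ({self.i}, {self.j})")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.i, self.j)

    def involves(self, position: int) -> bool:
        return position == self.i or position == self.j


@dataclass
class ContactMap:
    contacts: frozenset[Contact]
    params: Optional[ContactParams] = None

    def __post_init__(self):
        pairs = [(c.i, c.j) for c in self.contacts]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (i, j) pairs in contact map")
        self.contacts = frozenset(self.contacts)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(sorted(self.contacts))

    def of_residue(self, position: int) -> list[Contact]:
        return sorted(c for c in self.contacts if c.involves(position))


@dataclass
class RelationCounts:
    series: int = 0
    parallel: int = 0
    inverse_parallel: int = 0
    cross: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "series": self.series,
            "parallel": self.parallel,
            "inverse_parallel": self.inverse_parallel,
            "cross": self.cross,
        }


def compute_contacts(structure: Structure, params: ContactParams | str = "methods",
                     chain: Optional[str] = None) -> ContactMap:
    """Residue-residue contact map of a structure.

    A contact (i, j) is present iff residues at author positions i and j
    form at least ``min_atom_pairs`` atom-atom pairs within
    ``atom_dist_cutoff`` (inclusive) and |i − j| ≥ ``min_seq_sep``.
    """
    if isinstance(params, str):
        params = PRESETS[params]
    residues = [r for r in structure.residues(chain) if r.is_polymer]
    if len(residues) < 2:
        raise ValueError("need at least 2 polymer residues to compute contacts")

    coords, owner = [], []
    for idx, res in enumerate(residues):
        atoms = res.heavy_atoms() if params.heavy_only else res.atoms
        for a in atoms:
            coords.append(a.coords)
            owner.append(idx)
    coords = np.asarray(coords)
    owner = np.asarray(owner)

    tree = cKDTree(coords)
    pair_counts: dict[tuple[int, int], int] = {}
    for a_idx, b_idx in tree.query_pairs(params.atom_dist_cutoff):
        ra, rb = owner[a_idx], owner[b_idx]
        if ra == rb:
            continue
        key = (min(ra, rb), max(ra, rb))
        pair_counts[key] = pair_counts.get(key, 0) + 1

    contacts = set()
    for (ra, rb), n in pair_counts.items():
        pi, pj = residues[ra].seq_number, residues[rb].seq_number
        if pi > pj:
            pi, pj = pj, pi
        if n >= params.min_atom_pairs and abs(pj - pi) >= params.min_seq_sep:
            contacts.add(Contact(pi, pj, n_atom_pairs=n))
    return ContactMap(frozenset(contacts), params=params)


def relation(a: Contact, b: Contact) -> str:
    """Circuit-topology relation of contact ``a`` with respect to ``b``.

    P if a's interval lies strictly inside b's; P⁻¹ if a strictly contains
    b; S if the intervals are disjoint; X if they partially overlap;
    "concerted" if they share an endpoint. relation(a, b) == P iff
    relation(b, a) == P⁻¹; S and X are symmetric.
    """
    if (a.i, a.j) == (b.i, b.j):
        raise ValueError("relation is undefined for identical contacts")
    if len({a.i, a.j} & {b.i, b.j}) > 0:
        return CONCERTED
    if b.i < a.i and a.j < b.j:
        return PARALLEL
    if a.i < b.i and b.j < a.j:
        return INVERSE_PARALLEL
    if a.j < b.i or b.j < a.i:
        return SERIES
    return CROSS


def contact_count(cmap: ContactMap, position: int) -> int:
    """Number of distinct partner residues of ``position`` in the map."""
    partners = set()
    for c in cmap.contacts:
        if c.i == position:
            partners.add(c.j)
        elif c.j == position:
            partners.add(c.i)
    return len(partners)


def local_topology(cmap: ContactMap, position: int, count_pairs: bool = False) -> RelationCounts:
    """Local circuit topology of a residue.

    For each relation type R, counts contacts X not formed by the residue
    such that X stands in relation R to at least one contact C formed by
    the residue. The direction convention follows the folding reading: a
    residue on *inner* contacts of nested pairs has a high
    ``inverse_parallel`` count, because the outer contacts are in P⁻¹
    relation with its own.

    With ``count_pairs=True`` every (C, X) pair contributes instead of
    deduplicating X across the residue's contacts (sensitivity-analysis
    mode).
    """
    own = [c for c in cmap.contacts if c.involves(position)]
    counts = RelationCounts()
    seen: dict[str, set[Contact]] = {r: set() for r in RELATIONS}
    for other in cmap.contacts:
        if other.involves(position):
            continue
        for mine in own:
            rel = relation(other, mine)
            if rel == CONCERTED:
                continue
            if count_pairs:
                _bump(counts, rel)
            else:
                seen[rel].add(other)
    if not count_pairs:
        counts.series = len(seen[SERIES])
        counts.parallel = len(seen[PARALLEL])
        counts.inverse_parallel = len(seen[INVERSE_PARALLEL])
        counts.cross = len(seen[CROSS])
    return counts


def _bump(counts: RelationCounts, rel: str) -> None:
    if rel == SERIES:
        counts.series += 1
    elif rel == PARALLEL:
        counts.parallel += 1
    elif rel == INVERSE_PARALLEL:
        counts.inverse_parallel += 1
    elif rel == CROSS:
        counts.cross += 1


def brute_force_relations(cmap: ContactMap, limit: int = 200) -> dict[tuple[Contact, Contact], str]:
    """Full ordered-pair relation table by direct interval comparison.

    Independent code path from :func:`relation`; serves as the exhaustive
    oracle in tests. Size-limited because it is O(n²).
    """
    contacts = sorted(cmap.contacts)
    if len(contacts) > limit:
        raise ValueError(f"map exceeds brute-force limit of {limit} contacts")
    table: dict[tuple[Contact, Contact], str] = {}
    for a in contacts:
        for b in contacts:
            if a is b:
                continue
            sa, sb = {a.i, a.j}, {b.i, b.j}
            if sa & sb:
                label = CONCERTED
            else:
                inside_a = [p for p in (a.i, a.j) if b.i < p < b.j]
                inside_b = [p for p in (b.i, b.j) if a.i < p < a.j]
                if len(inside_a) == 2:
                    label = PARALLEL  # a entirely within b
                elif len(inside_b) == 2:
                    label = INVERSE_PARALLEL  # b entirely within a
                elif len(inside_a) == 0 and len(inside_b) == 0:
                    label = SERIES
                else:
                    label = CROSS
            table[(a, b)] = label
    return table


def relation_table_tsv(cmap: ContactMap) -> str:
    """Serialize the full ordered-pair relation table as TSV."""
    rows = ["a_i\ta_j\tb_i\tb_j\trelation"]
    for (a, b), label in sorted(brute_force_relations(cmap).items()):
        rows.append(f"{a.i}\t{a.j}\t{b.i}\t{b.j}\t{label}")
    return "\n".join(rows) + "\n"


def contact_map_tsv(cmap: ContactMap) -> str:
    rows = ["i\tj\tn_atom_pairs"]
    for c in cmap:
        rows.append(f"{c.i}\t{c.j}\t{c.n_atom_pairs}")
    return "\n".join(rows) + "\n"
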