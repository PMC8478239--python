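"""Per-variant feature assembly.

Builds the feature table consumed by the decision-tree classifier (and by
downstream ML users): externally supplied ΔΔG, ligand proximity, contact
count, catalytic-domain membership, local circuit-topology counts, Cα
B-factor, a 20-type contacting-residue profile, and an optional PSI-BLAST
PSSM row. ΔΔG is always an input — typically from a force-field style
predictor — never computed here.

All distance comparisons are inclusive (≤), matching the convention used
throughout the package. Missing optional inputs propagate as NaN, never as
silent zeros.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from pctopo.structure import Structure, ligand_atoms, ca_b_factor, THREE_TO_ONE
from pctopo.topology import ContactMap, contact_count, local_topology

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard types, one-letter, sorted

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})$")

_THREE_LETTER = {k.capitalize(): v for k, v in THREE_TO_ONE.items()}


@dataclass
class VariantRecord:
    """One missense variant with its externally supplied ΔΔG and label."""

    protein_id: str
    wt_aa: str  # one-letter
    position: int
    mut_aa: str  # one-letter
    ddg: float  # kcal/mol, positive = destabilising
    responsive: Optional[bool] = None
    label_source: str = ""

    def __post_init__(self):
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"{self.name}: wild-type and mutant residues are identical")

    @property
    def name(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @classmethod
    def from_string(cls, protein_id: str, variant: str, ddg: float,
                    responsive: Optional[bool] = None, label_source: str = "") -> "VariantRecord":
        """Parse "N370S" or HGVS-ish "p.Asn370Ser" into a record."""
        m = _VARIANT_RE.match(variant.strip())
        if not m:
            raise ValueError(f"cannot parse variant name {variant!r}")
        wt, pos, mut = m.groups()
        wt = _THREE_LETTER.get(wt.capitalize(), wt.upper()) if len(wt) == 3 else wt.upper()
        mut = _THREE_LETTER.get(mut.capitalize(), mut.upper()) if len(mut) == 3 else mut.upper()
        return cls(protein_id, wt, int(pos), mut, ddg, responsive, label_source)


@dataclass
class DomainConfig:
    """Catalytic-domain residue ranges (inclusive ends) per protein."""

    catalytic_ranges: list[tuple[int, int]]

    def __post_init__(self):
        ranges = sorted(self.catalytic_ranges)
        for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
            if a2 <= b1:
                raise ValueError("catalytic ranges must be non-overlapping")
        self.catalytic_ranges = ranges


def binds_ligand(structure: Structure, position: int, ligand_selector: str,
                 cutoff: float = 5.0, chain: Optional[str] = None) -> bool:
    """True iff any heavy atom of the residue is within ``cutoff`` Å
    (inclusive) of any ligand heavy atom."""
    res = structure.find_residue(position, chain)
    lig = ligand_atoms(structure, ligand_selector)
    res_xyz = np.array([a.coords for a in res.heavy_atoms()])
    lig_xyz = np.array([a.coords for a in lig])
    if res_xyz.size == 0 or lig_xyz.size == 0:
        return False
    return bool(cdist(res_xyz, lig_xyz).min() <= cutoff)


def in_catalytic_domain(config: DomainConfig, position: int) -> bool:
    if config is None:
        raise ValueError("no domain configuration provided")
    return any(a <= position <= b for a, b in config.catalytic_ranges)


def contact_profile(structure: Structure, cmap: ContactMap, position: int,
                    chain: Optional[str] = None) -> dict[str, int]:
    """Counts of contacting residues by amino-acid type.

    Returns a dict over the 20 standard one-letter types plus an "other"
    bin for non-standard partners (warned). The values sum to
    ``contact_count(cmap, position)``.
    """
    partners = set()
    for c in cmap.contacts:
        if c.i == position:
            partners.add(c.j)
        elif c.j == position:
            partners.add(c.i)
    profile = {aa: 0 for aa in AA_ALPHABET}
    profile["other"] = 0
    for p in sorted(partners):
        res = structure.find_residue(p, chain)
        one = THREE_TO_ONE.get(res.aa_type)
        if one is None:
            warnings.warn(f"non-standard contacting residue {res.aa_type} at {p}", stacklevel=2)
            profile["other"] += 1
        else:
            profile[one] += 1
    return profile


def read_pssm(path) -> pd.DataFrame:
    """Read a PSI-BLAST ASCII PSSM into a (positions × 20) DataFrame.

    Only the first matrix (integer log-odds) is consumed; the
    weighted-percentage matrix and trailing statistics block are ignored.
    The index holds 1-based query positions; columns are the 20 amino-acid
    letters in the file's own column order.
    """
    lines = Path(path).read_text().splitlines()
    header_cols: list[str] = []
    rows, index = [], []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            if rows:
                break  # blank line after data = end of matrix
            continue
        fields = stripped.split()
        if not header_cols:
            if len(fields) >= 20 and all(f in AA_ALPHABET for f in fields[:20]):
                header_cols = fields[:20]
            continue
        if not fields[0].isdigit():
            if rows:
                break  # statistics block
            continue
        if len(fields) < 22:
            raise ValueError(f"PSSM line {lineno}: truncated row ({len(fields)} fields)")
        try:
            scores = [int(x) for x in fields[2:22]]
        except ValueError as exc:
            raise ValueError(f"PSSM line {lineno}: non-integer score") from exc
        index.append(int(fields[0]))
        rows.append(scores)
    if not header_cols or not rows:
        raise ValueError(f"{path}: not a PSI-BLAST ASCII PSSM (no log-odds matrix found)")
    return pd.DataFrame(rows, index=pd.Index(index, name="position"), columns=header_cols)


FEATURE_COLUMNS = [
    "variant", "protein_id", "aa_from", "aa_to", "position",
    "ddg", "binds_ligand", "n_contacts", "catalytic_domain",
    "p_inv", "p_par", "series", "cross", "ca_b_factor",
]


def build_feature_table(
    variants: Sequence[VariantRecord],
    structure: Optional[Structure] = None,
    cmap: Optional[ContactMap] = None,
    ligand_selector: Optional[str] = None,
    domain_config: Optional[DomainConfig] = None,
    pssm: Optional[pd.DataFrame] = None,
    chain: Optional[str] = None,
    ligand_cutoff: float = 5.0,
    on_unresolved: str = "error",
) -> pd.DataFrame:
    """Assemble the per-variant feature table.

    Structure-derived columns are filled from ``structure``/``cmap`` when
    given; otherwise they are NaN (explicit missing values). With
    ``on_unresolved="skip"`` variants whose position is absent from the
    structure are dropped with a warning instead of raising.

    Raises if the wild-type residue recorded in a variant disagrees with
    the structure's sequence at that position.
    """
    records = []
    for v in variants:
        row: dict = {
            "variant": v.name, "protein_id": v.protein_id,
            "aa_from": v.wt_aa, "aa_to": v.mut_aa, "position": v.position,
            "ddg": v.ddg,
            "binds_ligand": np.nan, "n_contacts": np.nan, "catalytic_domain": np.nan,
            "p_inv": np.nan, "p_par": np.nan, "series": np.nan, "cross": np.nan,
            "ca_b_factor": np.nan,
        }
        if structure is not None:
            try:
                res = structure.find_residue(v.position, chain)
            except Exception:
                if on_unresolved == "skip":
                    warnings.warn(f"variant {v.name}: position not in structure; skipped",
                                  stacklevel=2)
                    continue
                raise
            if res.one_letter != "X" and res.one_letter != v.wt_aa:
                raise ValueError(
                    f"variant {v.name}: structure has {res.one_letter} at position {v.position}"
                )
            row["ca_b_factor"] = ca_b_factor(structure, v.position, chain)
            if ligand_selector is not None:
                row["binds_ligand"] = binds_ligand(
                    structure, v.position, ligand_selector, ligand_cutoff, chain)
        if cmap is not None:
            row["n_contacts"] = contact_count(cmap, v.position)
            lt = local_topology(cmap, v.position)
            row.update(p_inv=lt.inverse_parallel, p_par=lt.parallel,
                       series=lt.series, cross=lt.cross)
            if structure is not None:
                profile = contact_profile(structure, cmap, v.position, chain)
                row.update({f"contact_{aa}": n for aa, n in profile.items()})
        if domain_config is not None:
            row["catalytic_domain"] = in_catalytic_domain(domain_config, v.position)
        if v.responsive is not None:
            row["responsive"] = v.responsive
        if pssm is not None:
            if v.position in pssm.index:
                row.update({f"pssm_{aa}": pssm.at[v.position, aa] for aa in pssm.columns})
            else:
                row.update({f"pssm_{aa}": np.nan for aa in pssm.columns})
        records.append(row)
    if not records:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    return pd.DataFrame(records)


def read_variant_csv(path) -> list[VariantRecord]:
    """Read variants from CSV/TSV with columns protein_id, variant, ddg
    and optional label (yes/no, true/false, 1/0)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"protein_id", "variant", "ddg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant file missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        label = None
        if "label" in df.columns and pd.notna(r["label"]):
            label = str(r["label"]).strip().lower() in ("yes", "true", "1", "responsive")
        out.append(VariantRecord.from_string(
            str(r["protein_id"]), str(r["variant"]), float(r["ddg"]), label))
    return out
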