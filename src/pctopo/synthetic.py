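"""Synthetic inputs for exercising the pipeline end to end.

Three generators:

* toy structures whose contact map under the "methods" preset is known by
  construction — residues are tight 3-atom clusters placed either in
  contact (cluster centres 2.5 Å apart, all 9 atom pairs within 4.5 Å) or
  far apart (≥ 8 Å, no qualifying pairs);
* random contact maps paired with exhaustive relation tables, the oracle
  fixtures for the circuit-topology code;
* variant feature tables with responsiveness labels drawn from a stated
  logistic model, mirroring the empirical structure of the real datasets
  (destabilised and ligand-contacting and high-P⁻¹ variants are less
  likely to respond to chaperone treatment).

No physics anywhere: only inter-residue distances matter to the pipeline.
All randomness is behind explicit seeds; identical seeds give byte-
identical output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from pctopo.topology import Contact, ContactMap, PRESETS, brute_force_relations

#: per-residue atom offsets (Å) forming a tight cluster around each site
_ATOM_OFFSETS = np.array([[0.0, 0.0, 0.0], [0.8, 0.0, 0.0], [0.0, 0.8, 0.0]])
_ATOM_NAMES = ("CA", "CB", "CG")
_AA_CYCLE = ("ALA", "LEU", "GLY", "SER", "VAL", "THR", "LYS", "ASP", "PHE", "ARG")

_CONTACT_SEP = 2.5  # Å between contacting cluster centres
_FAR_SEP = 8.0  # Å between non-contacting neighbours
_JITTER = 0.05  # Å, seed-dependent; small vs the 4.5 Å cutoff margin

GEOMETRIES = ("extended", "hairpin", "nested-loops")


@dataclass(frozen=True)
class SyntheticStructureSpec:
    n_residues: int = 12
    geometry: str = "hairpin"
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("n_residues must be >= 3")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")


def _declared_contacts(spec: SyntheticStructureSpec) -> list[tuple[int, int]]:
    n = spec.n_residues
    min_sep = PRESETS["methods"].min_seq_sep
    if spec.geometry == "extended":
        return []
    if spec.geometry == "hairpin":
        return [(i, n + 1 - i) for i in range(1, n // 2 + 1) if (n + 1 - 2 * i) >= min_sep]
    # nested-loops: three concentric intervals
    if n < 12:
        raise ValueError("nested-loops geometry requires n_residues >= 12")
    return [(1, 12), (3, 10), (5, 8)]


def make_structure(spec: SyntheticStructureSpec) -> tuple[str, ContactMap]:
    """Generate PDB text plus the contact map it must produce under the
    "methods" preset. Deterministic per seed."""
    contacts = _declared_contacts(spec)
    n = spec.n_residues
    rng = np.random.default_rng(spec.seed)

    sites = {}
    for k, (i, j) in enumerate(contacts, start=1):
        sites[i] = np.array([0.0, 10.0 * k, 0.0])
        sites[j] = np.array([_CONTACT_SEP, 10.0 * k, 0.0])
    lonely = [r for r in range(1, n + 1) if r not in sites]
    for m, r in enumerate(lonely):
        sites[r] = np.array([100.0 + _FAR_SEP * m, 0.0, 0.0])

    buf = io.StringIO()
    serial = 1
    for r in range(1, n + 1):
        aa = _AA_CYCLE[(r - 1) % len(_AA_CYCLE)]
        for name, offset in zip(_ATOM_NAMES, _ATOM_OFFSETS):
            xyz = sites[r] + offset + rng.uniform(-_JITTER, _JITTER, size=3)
            x, y, z = np.round(xyz, 3)
            buf.write(
                f"ATOM  {serial:>5d}  {name:<3s} {aa:>3s} A{r:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{20.0:6.2f}           C\n"
            )
            serial += 1
    buf.write("TER\nEND\n")

    n_pairs = len(_ATOM_OFFSETS) ** 2
    expected = ContactMap(
        frozenset(Contact(i, j, n_atom_pairs=n_pairs) for i, j in contacts),
        params=PRESETS["methods"],
    )
    return buf.getvalue(), expected


def make_contact_maps(n_maps: int, n_contacts_max: int = 12, seed: int = 0,
                      n_positions: int = 30) -> list[tuple[ContactMap, dict]]:
    """Random duplicate-free contact maps paired with exhaustive relation
    tables (the brute-force oracle)."""
    if n_contacts_max > 200:
        raise ValueError("n_contacts_max exceeds the brute-force oracle limit")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_maps):
        n_contacts = int(rng.integers(0, n_contacts_max + 1))
        pairs: set[tuple[int, int]] = set()
        attempts = 0
        while len(pairs) < n_contacts and attempts < 50 * n_contacts_max:
            i, j = sorted(rng.choice(n_positions, size=2, replace=False) + 1)
            pairs.add((int(i), int(j)))
            attempts += 1
        cmap = ContactMap(frozenset(Contact(i, j) for i, j in pairs))
        out.append((cmap, brute_force_relations(cmap)))
    return out


#: default logistic coefficients on (1, ddg, binds_ligand, p_inv); the
#: signs encode the empirical directions: destabilisation, ligand contact
#: and high inverse-parallel counts all reduce the odds of responsiveness
DEFAULT_COEFS = {"intercept": 2.4, "ddg": -1.0, "binds_ligand": -2.0, "p_inv": -0.01}


@dataclass(frozen=True)
class SyntheticVariantSpec:
    n_variants: int = 2000
    coefs: dict = field(default_factory=lambda: dict(DEFAULT_COEFS))
    noise: float = 0.0  # sd of extra Gaussian noise on the logit
    seed: int = 0

    def __post_init__(self):
        missing = set(DEFAULT_COEFS) - set(self.coefs)
        if missing:
            raise ValueError(f"missing logistic coefficients: {sorted(missing)}")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")


def make_variant_table(spec: SyntheticVariantSpec) -> pd.DataFrame:
    """Sample a variant feature table with logistic responsiveness labels.

    Features: ddg ~ Normal(1.0, 1.5) kcal/mol, binds_ligand ~
    Bernoulli(0.15), p_inv ~ Poisson(120). The label is Bernoulli(p) with
    logit(p) = intercept + c_ddg·ddg + c_lig·binds_ligand + c_pinv·p_inv
    (+ Normal(0, noise) on the logit). Generator parameters are recorded
    in ``DataFrame.attrs["generator"]`` for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_variants
    ddg = rng.normal(1.0, 1.5, size=n)
    lig = rng.random(n) < 0.15
    p_inv = rng.poisson(120, size=n)
    c = spec.coefs
    logit = (c["intercept"] + c["ddg"] * ddg + c["binds_ligand"] * lig.astype(float)
             + c["p_inv"] * p_inv)
    if spec.noise > 0:
        logit = logit + rng.normal(0.0, spec.noise, size=n)
    p = 1.0 / (1.0 + np.exp(-logit))
    responsive = rng.random(n) < p

    df = pd.DataFrame({
        "variant": [f"V{i + 1}" for i in range(n)],
        "ddg": ddg,
        "binds_ligand": lig,
        "p_inv": p_inv,
        "p_true": p,
        "responsive": responsive,
    })
    df.attrs["generator"] = {"coefs": dict(c), "noise": spec.noise,
                             "seed": spec.seed, "n_variants": n}
    return df
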