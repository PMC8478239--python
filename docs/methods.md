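# Methods

## Scope and data flow

`pctopo` predicts whether a missense variant of a lysosomal enzyme will
respond to pharmacological chaperone treatment, from features computable
on a crystal structure plus an externally supplied ΔΔG of mutation. The
pipeline is: parse structure → compute residue contacts → derive
per-residue circuit-topology counts and other features → run the encoded
decision cascade → (optionally) interpret the topology dependence with an
ER kinetic model. ΔΔG computation, PSSM generation, tree training and
AutoML are deliberately outside the package: ΔΔG and PSSMs enter as plain
tabular/ASCII inputs, and the tree is a fixed published artefact.

## Structural model

PDB files are parsed with Bio.PDB. Alternate locations are collapsed to
the highest-occupancy conformer, ties broken by altloc identifier ("A"
first), so all geometry is single-conformer and deterministic. Residues
are identified by author chain/number/insertion code — the numbering
variant names like N370S use — and are never renumbered. Waters are never
ligand candidates; common monoatomic ions are excluded by default and can
be opted in. Hydrogens are parsed but excluded from heavy-atom queries.
A missing Cα B-factor propagates as NaN, never as a silent zero.

## Contacts

A contact between residues i and j requires at least `min_atom_pairs`
atom–atom pairs within `atom_dist_cutoff` (inclusive ≤, the single
boundary convention used package-wide) and |i − j| ≥ `min_seq_sep`.
Two published parameterisations exist and are both provided as presets:

| preset | cutoff | min pairs | atoms |
|---|---|---|---|
| `methods` | 4.5 Å | 5 | any type |
| `results` | 8.0 Å | 6 | heavy only |

Which of the two produced the published per-variant contact counts is not
stated in the source material, so neither preset is privileged; all
defaults and synthetic round-trips use `methods`, and the choice is a
parameter everywhere. `min_seq_sep` defaults to 2 (i, i+1 backbone
neighbours excluded), a choice made here since the source is silent.

## Circuit topology

For contacts a and b with intervals [a.i, a.j] and [b.i, b.j]:
relation(a, b) = P if a's interval lies strictly inside b's, P⁻¹ if it
strictly contains b's, S if the intervals are disjoint, X if they
partially overlap. Pairs sharing an endpoint are labelled *concerted* and
excluded from the four basic counts (a pair-level taxonomy of concerted
variants is not elaborated). relation(a, b) = P ⇔ relation(b, a) = P⁻¹;
S and X are symmetric; at the ordered-pair level the P and P⁻¹ totals of
a map are always equal.

The per-residue statistic, *local circuit topology*, counts for each
relation type the **distinct** contacts X (not formed by the residue)
standing in that relation to at least one contact the residue forms.
Distinct-contact counting was chosen over pair counting because the
statistic is described as a number of contacts; a pair-counting mode is
available behind `count_pairs=True` for sensitivity analysis. Contacts
formed by the query residue are excluded from its own counts. The
direction convention matters: a residue on the *inner* contact of a
nested pair gets inverse-parallel credit from the enclosing contact,
so early-folding (deeply enclosed) residues have high P⁻¹ counts.

`brute_force_relations` re-derives every ordered-pair label by direct
endpoint comparison through an independent code path and is the
exhaustive oracle for the fast implementation (1,000 random maps of up to
12 contacts in the acceptance suite).

## Feature assembly

Per variant: ΔΔG (kcal/mol, input), ligand contact (any heavy atom of the
residue within 5 Å, inclusive, of any ligand heavy atom), contact count,
catalytic-domain membership (user-supplied inclusive residue ranges, as
the published domain boundaries are procedural rather than printed),
local-topology counts, Cα B-factor, a 20-type contacting-residue profile
(non-standard partners land in an "other" bin with a warning; the profile
always sums to the contact count), and optionally a PSI-BLAST ASCII PSSM
row (only the first, log-odds matrix of the two-matrix layout is read).
Missing optional inputs yield NaN columns; a wild-type mismatch between a
variant record and the structure sequence is an error naming the residue
found.

## The decision cascade

Node order follows the published narration: ΔΔG root → ligand → contact
count → ΔΔG window → inverse-parallel count. Published thresholds:
1.7 kcal/mol (≥ → non-responsive), 0.94 (< → responsive), −1.4 (≤ →
non-responsive). Two thresholds are not printed anywhere: the
small-contact cutoff (the worked examples only constrain it to (3, 5]; 4
is used, strict less-than) and the inverse-parallel cutoff (any value in
[1, 219] is admissible; 100 is used, ≥ fires non-responsive). Both are
configurable, and the test suite verifies that every admissible value
reproduces the worked examples — the published calls do not sit on a
knife edge. Published leaf probabilities exist for three leaves
(small_contacts 0.60, root_destab 0.28, pinv_high 0.34); the other four
leaves default to the class-typical published values (0.60/0.28), are
flagged as placeholders, and can be overridden in the CLI config.

## ER kinetics

Species U (unfolded, supplied at rate P, degraded at k_p·U), F (folded),
F_B (chaperone-bound), E (exported); transitions k_f, k_u, kon_L (an
effective pseudo-first-order binding rate, on-rate × ligand
concentration), k_off, and export k_out from both F and F_B. The linear
system gives, with A = k_u + kon_L + k_out − k_off·kon_L/(k_off + k_out):

    F   = k_f·P / [ (k_p + k_f)·A − k_f·k_u ]
    F_B = kon_L·F / (k_off + k_out)
    U   = (P + k_u·F) / (k_p + k_f)
    dE/dt = k_out·(F + F_B)

The closed form is validated against numerical integration of the four
ODEs (LSODA, rtol 1e−10) to 1e−6 relative on random positive-rate grids;
mass balance P = k_p·U + dE/dt holds to 1e−10 and the binding identity
F_B·(k_off + k_out) = kon_L·F exactly. Default rates: P = 0.1, k_p = 10,
k_f = 10, k_u = 0.01, k_out = 0.01; chaperone on = (kon_L, k_off) =
(0.1, 0.01), chaperone off = (1e−5, 1e−5) — the published
parameterisation of "no chaperone" as numerically tiny rather than zero
is kept, with literal zero also supported. All rates are in arbitrary
reciprocal-time units; only ratios matter for the qualitative ordering.

Mutations map to rates through ΔΔG = 4.0963 − 0.593·ln(k_f/k_u); the
constant makes the wild-type rates the ΔΔG ≈ 0 reference
(0.593·ln(1000) ≈ 4.0961) and is used verbatim. Mode "unfolding" (φ = 0)
expresses the destabilisation entirely in k_u; mode "folding" (φ = 1)
entirely in k_f; fractional φ is out of scope. The reproduced ordering is
qualitative — no numeric flux values are published — and is asserted as
two inequalities over a 50-point destabilising ΔΔG grid: chaperone-on
flux ≥ chaperone-off flux everywhere, and the rescue ratio
(on/off) of unfolding-mode mutants ≥ that of folding-mode mutants at
matched ΔΔG.

## Synthetic data

The generator produces the three kinds of inputs the pipeline consumes,
with known ground truth and no physics:

- **Structures**: residues are tight 3-atom clusters; contacting pairs
  sit 2.5 Å apart (all 9 atom pairs within 4.5 Å, comfortably over the
  ≥ 5-pair threshold), non-contacting residues ≥ 8 Å apart, with a
  seed-dependent ±0.05 Å jitter small against those margins. Geometries:
  `extended` (no contacts), `hairpin` (i paired with n+1−i), and
  `nested-loops` (three concentric intervals, giving a pure
  inverse-parallel chain for the innermost residue). The declared contact
  set is recovered exactly by the real contact code under the `methods`
  preset — a round-trip through PDB text, the parser, and the KD-tree
  pair counting.
- **Contact maps**: uniformly sampled duplicate-free interval sets (≤ 12
  contacts over 30 positions) paired with exhaustive relation tables.
- **Variant tables**: ddg ~ Normal(1.0, 1.5) kcal/mol, ligand contact ~
  Bernoulli(0.15), P⁻¹ ~ Poisson(120); responsiveness ~ Bernoulli(p) with
  logit(p) = 2.4 − 1.0·ddg − 2.0·ligand − 0.01·P⁻¹ (optionally plus
  Gaussian logit noise, default 0). The coefficient signs encode the
  empirical directions (destabilisation, ligand contact and high P⁻¹ all
  reduce responsiveness); magnitudes were chosen once to give a roughly
  balanced label split and a clearly separated ΔΔG difference between
  classes at n = 2,000. Generator parameters are recorded in the output
  metadata, and a 10,000-row logistic refit recovers every coefficient
  within 3 standard errors.

What passing synthetic tests do *not* show: real proteins have dense,
irregular contact networks, correlated features, heterogeneous B-factors
and assay noise; the synthetic structures only certify the geometric and
combinatorial bookkeeping, and the variant tables only certify the
statistical plumbing, not biological validity.

## Metrics

MCC is computed from the confusion table by the direct Matthews formula
(zero denominator → 0, the common convention; the source is silent). AUC
is the rank-based Mann–Whitney statistic with midrank tie handling,
via scikit-learn. The test suite cross-checks MCC against scikit-learn's
implementation on random label vectors.

## Numerical and interface choices

- All distance boundaries are inclusive (≤), stated once and used
  everywhere.
- Problem sizes in the default test run: 1,000 random contact maps for
  the topology oracle, 100 random rate sets (10 with full ODE
  integration) for the kinetics checks, 2,000–10,000 rows for the
  synthetic-variant statistics. The whole suite runs in well under a
  minute.
- The CLI emits results on stdout or `--out` files only; logs go to
  stderr. Feature and prediction outputs are accompanied by a provenance
  JSON (package version, input SHA-256 hashes, parameters). Re-runs with
  identical inputs are byte-identical.

## Known limitations

- The two published contact definitions disagree and the provenance of
  the published per-variant contact/P⁻¹ counts is unknown; recomputing
  those counts from the crystal structure is therefore not an acceptance
  surface, and the bundled reference table carries the printed values.
- Four of seven leaf probabilities and two of five tree thresholds are
  unpublished; defaults are documented guesses constrained by the worked
  examples.
- The kinetic model is two-state with integer φ, deterministic and
  linear; no multi-state folding, fractional φ, or stochastic dynamics.
- Evaluation against the full Fabry/Pompe datasets requires external data
  and is out of scope; only the operations (MCC, AUC, confusion counts)
  are provided.
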