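# pctopo

Structure-based triage of missense variants for **pharmacological
chaperone (PC) responsiveness** in lysosomal enzymes (glucocerebrosidase /
Gaucher disease, α-galactosidase A / Fabry, acid α-glucosidase / Pompe).

A pharmacological chaperone is a small molecule that binds and stabilises
the folded state of a destabilised mutant enzyme in the endoplasmic
reticulum (ER), improving folding and trafficking to the lysosome. Only
some missense variants respond. This package implements a pipeline that
predicts responsiveness from structural features of the mutated residue:

- **Contact extraction** from PDB structures. Two published residue-contact
  definitions are provided as presets: `"methods"` (≥ 5 atom–atom pairs of
  any type within 4.5 Å) and `"results"` (≥ 6 heavy-atom pairs within 8 Å).
- **Circuit topology** of the contact map. Every pair of contacts with
  sequence intervals [i, j] and [k, l] is in *series* (S, disjoint
  intervals), *parallel* (P, one nested strictly inside the other) or
  *cross* (X, partial overlap); the outer contact of a nested pair is in
  *inverse parallel* (P⁻¹) with the inner one. The per-residue "local
  circuit topology" counts, for each relation type, the contacts standing
  in that relation to any contact formed by the residue. A residue sitting
  on inner contacts — presumed early to fold — accumulates a high P⁻¹
  count.
- **A decision-rule classifier** (an encoded published tree, not refit):
  ΔΔG ≥ 1.7 kcal/mol → non-responsive; ligand contact → non-responsive;
  < 4 contacts → responsive; ΔΔG ≤ −1.4 → non-responsive; ΔΔG < 0.94 →
  responsive; else P⁻¹ ≥ threshold → non-responsive. Leaves carry a
  probability of responsiveness, p1.
- **An ER kinetic model**: unfolded protein U is produced at rate P,
  degraded at k_p·U, folds at k_f; folded F unfolds at k_u, binds the
  chaperone at kon_L, dissociates at k_off, and is exported (along with
  the bound form F_B) at k_out. The closed-form steady-state export flux
  dE/dt = k_out·(F + F_B) is the readout. Mapping mutations to rates via
  the two-state relation ΔΔG = 4.0963 − 0.593·ln(k_f/k_u) shows that
  mutants that speed unfolding (φ = 0) are easier to rescue than mutants
  that slow folding (φ = 1) at matched ΔΔG — the kinetic rationale for the
  P⁻¹ dependence of the classifier.

ΔΔG values are always *inputs* (e.g. from a force-field predictor); the
package never computes them.

## Worked example

The bundled reference dataset contains the published feature values for
seven Gaucher-disease variants. Running the classifier:

```python
from pctopo.datasets import load_gaucher_variants
from pctopo.tree import predict_batch, evaluate

df = load_gaucher_variants()
preds = predict_batch(df)
print(preds[["variant", "responsive", "p1", "leaf_id"]].to_string(index=False))
```

prints

```
variant  responsive   p1        leaf_id
  N370S        True 0.60 small_contacts
  L444P       False 0.28    root_destab
  G202R        True 0.60 small_contacts
  F213I       False 0.34      pinv_high
  R120W       False 0.28    root_destab
  N188S        True 0.60 small_contacts
  D409H        True 0.60 small_contacts
```

N370S and G202R are called responsive and L444P non-responsive — all
three consistent with the cell-based assay against
N-nonyl-deoxynojirimycin. `evaluate(preds["responsive"],
df["observed_responsive"])` reports 4 of 7 correct overall: on the
harder Ambroxol panel (last four variants) only N188S is called
correctly, matching the known behaviour of the single tree.

The same pipeline is available from the shell:

```
pctopo make-synthetic --kind structure --geometry nested-loops --n 12 --seed 1 --out syn.pdb
pctopo topology --pdb syn.pdb --residue 5 --preset methods
pctopo kinetics --ddg-min 0 --ddg-max 4 --step 0.05 --out sweep.csv --plot sweep.png
```

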