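# ligeval

Assessment toolkit for blind protein–ligand **pose** and **affinity**
prediction challenges. It re-implements, as a reusable and tested pipeline,
the evaluation machinery used to assess community docking/co-folding
challenges:

* **Pose metrics** — binding-site superposed, symmetry-corrected ligand RMSD;
  LDDT-PLI (contact-preservation score with a penalty for predicted contacts
  absent from the crystal); BB-RMSD and LDDT-LP for binding-site structure
  accuracy. Multiple reference ligand copies, alternate conformations, ligand
  graph automorphisms and chain-swap symmetry are all handled by best-score
  selection.
* **Group aggregation** — skip-penalized mean LDDT-PLI, skip-penalized
  RMSD ≤ 2.5 Å success rate, best-of-models statistics, rankings, per-target
  difficulty, and reliability-score (LScore) evaluation by Kendall's τ.
* **Affinity assessment** — absolute/relative/rank submissions normalized to
  rankings, tie-corrected Kendall's τ against IC50-derived free energies,
  N-weighted τ across supertargets, descriptor baselines, Stage 1 vs Stage 2
  comparison, and a resampling-based **experimental-noise ceiling** (the best
  τ even a perfect predictor could reach given Gaussian noise on ΔG = RT·ln IC50).
* **Template similarity** — SuCOS-style ligand overlap (Gaussian shape ×
  pharmacophore features) multiplied by binding-pocket coverage under a
  supplied residue alignment.
* **Synthetic data** — fully deterministic generators for miniature reference
  complexes, perturbed poses, multi-group submission cohorts and affinity
  datasets with known ground truth, emitting the same on-disk layout the
  readers consume.

## Command-line usage

A single `ligeval` entry point with subcommands. A typical closed loop on
synthetic data:

```bash
# 1) generate a fixture tree (references + submissions + affinity tables)
cat > spec.yaml <<'EOF'
cohort:
  n_targets: 10
  seed: 1
  groups:
    - {group_id: 1, sigma_pose: 0.4, skip_prob: 0.0, lscore_rho: 0.9}
    - {group_id: 2, sigma_pose: 2.5, skip_prob: 0.2}
affinity:
  n: 40
  dg_span: 5.4
  sigma_exp: 0.66
  group_sigmas: [0.3, 2.0]
  seed: 1
EOF
ligeval simulate --spec spec.yaml --out fixtures/

# 2) score every (group, target, model) against the references
ligeval score-poses --refs fixtures/references --subs fixtures/submissions \
    --manifest fixtures/manifest.yaml --out scores.csv

# 3) group rankings (skip-penalized LDDT-PLI / success rate / best-of-models)
ligeval rank --scores scores.csv --manifest fixtures/manifest.yaml --out ranks/ --plots

# 4) affinity τ tables, N-weighted τ, noise ceilings at σ = 0.66 and 2 kcal/mol
ligeval affinity --measurements fixtures/affinity_measurements.csv \
    --predictions fixtures/affinity_predictions.csv --out affinity/ --seed 1

# 5) template similarity for one target/template pair
ligeval similarity --target fixtures/references/T0001 \
    --template fixtures/references/T0002 --alignment aln.csv --out sim.csv
```

All commands are deterministic given `--seed`; reports embed the package
version and the fully resolved configuration; unknown config keys are
rejected.

## Layout

```
src/ligeval/
  structures.py   PDB/SDF/SMILES I/O, domain types, submission trees
  pose.py         binding site, Kabsch, automorphisms, RMSD + LDDT metrics
  aggregate.py    skip-penalized statistics, rankings, LScore reliability
  affinity.py     τ machinery, N-weighted τ, resampling ceiling, baselines
  similarity.py   SuCOS-style overlap × pocket coverage
  synthetic.py    deterministic toy-complex / cohort / affinity generators
  challenge.py    published dataset composition tables (counts, blacklists)
  config.py       validated run configuration
  plots.py        optional report figures
  cli.py          the ligeval command-line interface
```
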