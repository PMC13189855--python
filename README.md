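# rnpqa

Single-model quality assessment for protein–RNA complex structural models.

Given one structural model of a protein–RNA complex (no native structure
required), a residue-graph transformer predicts, in one pass:

- three global **fold** estimates — backbone lDDT, GDT-TS, GDT-HA;
- three global **interface** estimates — iLDDT, IPS (interface patch
  similarity, a Jaccard index over interface residues), ICS (interface
  contact score, an F1 over inter-chain residue contacts);
- two estimates (**IPS, ICS**) for every protein–RNA interface.

These are averaged into six combined scores (`fold`, `iface`, `merged`,
`rp`, and per-interface `perif` / `perif_g`) used to rank and select
models. The package is aimed at structural bioinformaticians who score
docking decoys or prediction ensembles: it also computes the ground-truth
metrics against a reference (bb-lDDT, iLDDT, ICS, IPS, a protein–RNA
iRMSD and single-superposition GDT approximations), the benchmark
statistics used to compare predictors (ranking loss, outlier-robust
Z-scores with the 0.3 fold / 0.7 interface block weighting, quantile-based
selection metrics), and a synthetic graded-decoy generator that makes the
whole pipeline trainable and testable on a laptop CPU.

## Model sketch

A model is encoded as a graph: residues are nodes (66 feature channels:
identity, torsions, secondary structure, solvent accessibility,
center-of-mass geometry, pairing/element annotations, interface and
polymer indicators), and edges (12 channels) join residues with anchor
atoms (Cβ/Cα, C3′) within 14 Å or any heavy atoms within 6 Å. Three
network components — global multi-head attention fused with local
edge-featured aggregation, then two rounds of attention-weighted message
passing, the last one on the graph pruned to protein–RNA edges — each end
in learned top-k pooling. Three global-attention-pooling heads emit the
sigmoid quality estimates. Training minimizes a multi-task L1 loss against
reference-derived labels with stratified k-fold ensembling. See
`docs/methods.md` for the full account.

## Worked example

```bash
python examples/score_a_model.py
```

builds a small synthetic complex (12 amino acids docked against 8
nucleotides), featurizes it and scores it with a freshly initialized
network:

```
graph: 20 residues, 114 edges, 8 interface residues, interfaces [('A', 'R')]
raw fold predictions  (bb-lDDT, GDT-TS, GDT-HA): [0.462 0.524 0.549]
raw iface predictions (iLDDT, IPS, ICS):         [0.49  0.428 0.518]
...
            fold = 0.512
           iface = 0.479
          merged = 0.495
              rp = 0.438
```

Each combined score is the mean of the raw sigmoid outputs above it (all
in (0,1), higher = better predicted quality); an untrained network gives
mid-range values, and `examples/train_toy_ensemble.py` shows the scores
becoming informative after a few epochs on graded decoys. The other
examples demonstrate the ground-truth metrics
(`ground_truth_metrics.py`), the decoy generator's monotone degradation
(`graded_decoys.py`) and the ranking statistics
(`ranking_statistics.py`).

A thin CLI wraps the same library calls:

```bash
rnpqa gen-decoys --n-decoys 20 --seed 1 --outdir decoys/   # PDBs + labels
rnpqa truth decoys/decoy_*.pdb -r decoys/native.pdb        # ground truth TSV
rnpqa score decoys/decoy_0001.pdb                          # predicted scores
```

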