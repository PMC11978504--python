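# contextmpnn

Ligand-context-conditioned protein sequence design and sidechain packing.

The package implements an invariant graph featurization of protein backbones
plus nonprotein atoms (small molecules, nucleotides, metals, donated
sidechain atoms), a three-block message-passing encoder/decoder that designs
sequences autoregressively under a random decoding order, and a sidechain
packing head that decodes chi angles from three-component circular-normal
(von Mises) mixtures. Training, sampling, scoring, and the evaluation
metrics (context-shell sequence recovery, chi-within-10° recovery,
confidence calibration) are included, along with a synthetic-fixture module
that makes everything testable end to end without any external data.

The networks run on a small numpy reverse-mode autodiff core
(`contextmpnn.nn.tensor`), so the package needs no deep-learning framework.
At default configuration the full model has 2,618,693 trainable parameters
(2.62 M) and the protein-only ablation 1,660,485 (1.66 M).

## Layout

| module | role |
| --- | --- |
| `structures_io` | PDB/mmCIF parsing (biotite-backed), FASTA/PDB/JSON writers |
| `featurization` | virtual-CB construction, k-NN protein graph, 25 atom-pair RBF blocks, positional encodings, per-residue context-atom selection, element/angle features, coordinate noise |
| `nn` | autodiff core, layers, the three message-passing layer types, encoder, sequence decoder, torsion head, checkpoints |
| `design` | sampling with temperature/bias, fixed positions, tied groups, teacher-forced scoring |
| `packing` | von Mises mixture prediction, four-stage chi decoding with coordinate feedback, ideal-geometry kinematics |
| `training` | losses, sidechain-context augmentation, token-budget batching, Adam training loop, recovery evaluation |
| `metrics` | context-shell membership, sequence/chi recovery, confidence calibration |
| `fixtures` | synthetic backbones, ligand clouds, planted-rule datasets |

## CLI

```bash
contextmpnn design --structure input.pdb --out-fasta designs.fasta \
    --n-designs 10 --temperature 0.1 --seed 1 --out-json designs.json
contextmpnn score  --structure input.pdb --sequence MKTAYIAK... --n-orders 4
contextmpnn pack   --structure input.pdb --sequence MKTAYIAK... \
    --out-pdb packed.pdb --mode mode --seed 1
contextmpnn fixtures generate --out-dir fixtures/ --n-structures 4 --seed 0
```

Without `--checkpoint` the commands run with freshly initialized (untrained)
weights; pass a checkpoint produced by `contextmpnn.training.train` for
meaningful designs.

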