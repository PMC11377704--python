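# plmfuse

Per-residue protein prediction from protein language model (pLM)
embeddings, with five ways of bringing in the evolutionary information of a
protein family — and the tooling needed to compare them fairly.

## The problem

For three decades, multiple sequence alignments (MSAs) were the key input
for predicting protein structure and function: the column statistics of a
family of homologs encode which positions are conserved and which covary.
Embeddings from pLMs (SeqVec-, ProtBert-, ProtT5-style models) have
recently replaced MSAs as the standard per-residue input. A natural
question for anyone building residue-level predictors (secondary
structure, binding, transmembrane topology, disorder, conservation) is
whether combining both inputs helps, and where in the pipeline the family
signal should enter. `plmfuse` implements the five candidate strategies as
one pipeline over a shared per-residue CNN, so that performance
differences are attributable to the inputs rather than model capacity:

| workflow | family signal enters | model input |
|---|---|---|
| `raw` | — | L×D embedding of the query |
| `msa-emb` | before the model | embeddings averaged column-wise over the MSA |
| `msacons` | after the model | predictions averaged column-wise over the MSA |
| `pssm-concat` | beside the embedding | L×(D+20): embedding ∥ PSSM |
| `pssm-split` | beside the embedding | two CNN branches, merged mid-network |

Here D is the embedding width, and the PSSM is a per-position 20-dim
amino-acid profile computed from the MSA columns with a pseudocount.

The package also provides:

- **Redundancy-reduced data splitting** on the HSSP curve. For a pairwise
  alignment with `L` match states and `n_ident` identities,
  `PIDE = 100·n_ident/L` and

  `HVAL = PIDE − {100 (L ≤ 11); 480·L^(−0.32·(1+exp(−L/1000))) (11 < L ≤ 450); 19.5 (L > 450)}`.

  `HVAL ≤ 0` marks a pair safe to separate across train/val/test; the
  splitter additionally caps train-internal identity at PIDE ≤ 70 and a
  leakage check verifies every cross-partition pair sits below 30%
  identity.
- **Evaluation**: per-residue Q3, per-protein Q10, precision/recall/F1,
  Spearman's ρ for continuous targets, conservation MCC (nine classes
  binarized at >5), and the per-segment Q_ok under the ±5-residue /
  half-of-union segment matching rule; per-chain aggregation with
  SE = SD/√(n−1); shuffle-label and majority-class baselines.
- **A synthetic family generator** producing homolog families with
  controlled pairwise identity, per-residue labels conserved across the
  family, and embeddings equal to a label-dependent signal plus Gaussian
  noise — so the whole pipeline, including the denoising effect of MSA
  averaging, is testable end to end without any downloads.

## Worked example

Train a raw-embedding model and an MSA-averaged-embedding model on
synthetic families with noisy embeddings (σ = 3 per coordinate against a
unit class separation), then score both on held-out families:

```python
from plmfuse.pipeline import msa_denoising_contrast

result = msa_denoising_contrast(sigma=3.0, seed=1)
print(f"raw Q3     {result.q3_raw:.1f}")
print(f"msa-emb Q3 {result.q3_msa:.1f}")
print(f"gain       {result.gain:.1f}")
```

Output:

```
raw Q3     46.6
msa-emb Q3 90.8
gain       44.2
```

Averaging embeddings over ~50 homologs whose labels are conserved divides
the noise variance by ~50, so the noisy embeddings become nearly
separable — the per-residue accuracy (Q3) jumps by 44 points. Re-running
with `sigma=0.1` gives 99.9 vs 100.0: clean embeddings have nothing left
to gain from the family, which mirrors what happens when averaging is
applied to modern pLMs. (The shuffle-label baseline for three equally
likely states is 33.3.)

The same pipeline runs from the shell:

```bash
plmfuse simulate --out bench --n-train 20 --n-val 5 --n-test 5 --sigma 3
plmfuse run-all --config config.yaml --out results/
plmfuse predict --workflow msa-emb --fasta queries.fasta \
    --msa-dir msas/ --embeddings emb.h5 --model model.npz --out tracks.tsv
plmfuse evaluate --pred tracks.tsv --labels labels.tsv --out perchain.tsv
```

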