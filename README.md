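# seqdsn

Domain-separation transfer learning for RNA 5-methyluridine (m5U) site
prediction from sequence windows.

## The problem

m5U is one of the most abundant non-canonical bases on tRNA, but on
mRNA only a few hundred sites have been mapped (miCLIP / FICC-seq) —
too few to train a dedicated mRNA predictor well. `seqdsn` treats this
as transfer learning: tRNA and other non-mRNA sites are a label-rich
**source domain**, mRNA sites the scarce **target domain**, and a
domain-separation network (DSN) learns the sequence features the two
domains *share* while quarantining what is domain-specific.

Three encoders (CNN + LSTM) map a 41-nt uridine-centred one-hot window
x to 16-dimensional representations: a shared encoder E_c used by both
domains and a private encoder per domain E_p. Per-domain decoders
reconstruct x from h_p + h_c, and classifiers read only h_c. Training
minimises

    L = α·L_recon + β·L_difference + γ·L_similarity + L_source + δ·L_target

(α = 0.02, β = 0.075, γ = 0.25, δ = 1), where L_difference pushes h_c
and h_p toward orthogonal subspaces, L_similarity (multi-kernel MMD, or
adversarial DANN) keeps the two domains' shared representations
distributionally alike, and the classification terms are class NLLs —
the target term existing only in the dual-classifier mode. When no mRNA
positive is available at all (mode 1), the target stream carries only
mRNA negatives as sequence context.

The package ships the complete pipeline: FASTA / site-table I/O and
window encoding, transcript-level negative sampling (1:10 for mRNA, all
undetected uridines for tRNA), the 6 × 6 = 36-fold cross-validation
design, a synthetic paired-domain benchmark generator with planted
motifs, training with the step-decay schedule and best-epoch keeping,
the Acc/Spe/Pre/F1/AUC/AP metric suite with classical baselines, and
Integrated-Gradients motif mining.

## Worked example

`examples/02_train_and_transfer.py` trains on a reduced synthetic
benchmark in ~40 s and prints:

```
predictor                        AUC      AP
source-only logistic           0.546   0.097
mode 1 (no target labels)      0.922   0.681
mode 2 (dual classifier)       0.952   0.855

transfer gain (mode 1 over baseline): +0.376 AUC
```

All three predictors see the same held-out mRNA-like test split (1:10
positives to negatives). The logistic baseline trained on source data
only is misled by a source-private confounder motif and the background
composition shift; the DSN trained *without a single target positive
label* (mode 1) transfers the shared motif and gains +0.38 AUC, and
adding the scarce target positives as a second supervision signal
(mode 2) lifts average precision further — the ordering the method is
designed to produce. `examples/04_motif_discovery.py` then recovers the
planted shared motif from the trained model's attributions:

```
motif 1: consensus CCGUUCGAUAA  support 60  mean weight 0.627
```

(the generator planted `GUUCGA` in every positive of that preset).

The other examples cover the benchmark generator
(`01_simulate_benchmark.py`) and the grouped cross-validation design
(`03_cross_validation.py`).

## Command line

The same pipeline is scriptable from a shell:

```bash
seqdsn simulate --preset confounded --seed 0 --out data/
seqdsn train --source-fasta data/source.fasta --source-sites data/source_sites.tsv \
             --target-fasta data/target.fasta --target-sites data/target_sites.tsv \
             --mode 1 --out run/
seqdsn evaluate --model run/model.npz --fasta data/target.fasta \
                --sites data/target_sites.tsv --out metrics.json
seqdsn cv ... --groups 6 --out cv/        # 36-fold report
seqdsn interpret --model run/model.npz ... --out motifs/
```

Results go to files; stdout carries one machine-readable JSON summary
per run; logs go to stderr.

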