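# epicore

Prediction of MHC class II binding cores from experimentally mapped
epitopes, for immunologists and bioinformaticians working on
autoimmune-disease antigens — in particular the type 1 diabetes pair of
the NOD-mouse I-A<sup>g7</sup> molecule and its human analogue HLA-DQ8.

Experimentally identified class II epitopes are peptides of roughly
9–30 aa, but recognition runs through a fixed 9-residue register in the
binding groove. `epicore` implements the full workflow around that fact:

1. **Core alignment (Gibbs sampling).** Given epitopes S₁…S_N, one
   9-mer window P_i is kept per epitope. Starting from random windows,
   epitopes are revisited in random order and P_i is moved to the window
   maximizing Score(P_i) = mean over j≠i of S(P_i, P_j), until a full
   pass changes nothing (with multiple restarts to escape phase-shifted
   local optima). The objective is the average substitution-matrix
   similarity, not a PSSM frequency ratio.
2. **Similarity scoring.** For nonamers A, B:
   S′(A,B) = Σᵢ wᵢ·Score(A[i],B[i]), clamped to 0 if negative
   (BLOSUM62 by default, unit weights initially). A query is scored
   against a model as the average clamped similarity over all training
   cores.
3. **Greedy training.** Weight training (WT) perturbs one of the nine
   position weights by ±1; matrix mutation (MaM) perturbs one
   substitution-matrix entry by ±1 (symmetrically). A move is kept only
   if leave-one-out sensitivity at 90% specificity strictly increases.
4. **Evaluation and calibration.** Sn/Sp/Ac/MCC, ROC and AROC, LOO and
   repeated stratified n-fold cross-validation, cross-haplotype
   evaluation, and three specificity-anchored score cutoffs
   (high/medium/low at Sp = 97/95/90%, medium being the default tier).
5. **Prediction.** Sliding-window scan of protein FASTA; windows scoring
   strictly above the cutoff are reported, and an epitope counts as hit
   when a predicted nonamer lies fully inside its span.

A first-class synthetic-data generator produces motif-implanted
epitopes, host proteins and labeled nonamer sets with known ground
truth, so every stage is testable without downloads.

## Worked example

```python
import numpy as np
import epicore as ec

# synthetic study set: 50 epitopes (12-25 aa), one implanted core each,
# dominant P9 anchor with P8/P4 companions at strength 0.9
profile = ec.generate_motif(anchor_strength=0.9, rng=np.random.default_rng(2024))
proteins, epitopes, truth = ec.generate_epitope_set(profile, 50, (12, 25), seed=6)

# align epitopes to 9-mer cores
prepared = [x for x in (ec.extend_short_epitope(e, proteins[e.protein_id])
                        for e in epitopes) if x is not None]
cores = ec.sample_cores(prepared, ec.load_substitution_matrix(),
                        ec.GibbsConfig(seed=1, restarts=5))
recovered = np.mean([prepared[a.epitope_index].start + a.offset == t.core_start
                     for a, t in zip(cores.assignments, truth.epitopes)])
print(f"recovered {100*recovered:.0f}% of implanted core offsets")

# train on unique cores vs negative windows from the host proteins
negatives = [w.sequence for w in ec.build_negative_set(proteins, prepared)]
model = ec.train_model(cores.unique_cores, negatives,
                       ec.TrainingConfig(seed=2, patience=200, max_proposals=2000))
print(f"medium-tier cutoff: {model.thresholds['medium']:.4f}")

# predict binding cores in a protein
hits = ec.scan_protein(proteins["SYNP0001"], model, tier="medium")
for h in hits[:3]:
    print(f"{h.start:>4} {h.end:>4}  {h.peptide}  {h.score:.4f}")
```

Output (seed-exact):

```
recovered 98% of implanted core offsets
medium-tier cutoff: 1.4800
   7   15  ACTHMNDIS  1.5000
  30   38  GEWRWTWRC  4.0000
  51   59  LEGRVMFFC  11.6000
```

The recovery line says the sampler found 49 of 50 implanted binding
registers; the cutoff is the score above which a window is called at the
default (medium, Sp ≈ 95%) tier; each hit line is a predicted core with
its 1-based span and model score. The top-scoring window (51–59,
LEGRVMFFC) is exactly the core implanted into this protein; the two
weaker calls are the false-positive load the 95%-specificity tier
permits.

The same pipeline is available from the shell:

```sh
epicore simulate -o sim --n 50 --seed 6
epicore cores sim.epitopes.tsv --proteins sim.fasta -o cores.tsv --seed 1
epicore train cores.tsv --proteins sim.fasta --epitopes sim.epitopes.tsv -o model.txt
epicore predict model.txt sim.fasta -o predictions.tsv --tier medium
```

For real data, supply the curated epitope table as TSV
(`protein_id  start  end  peptide  haplotype`, 1-based inclusive spans)
together with the source proteins as FASTA.

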