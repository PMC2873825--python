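# gacontact

Prediction of long-range inter-residue contacts in protein chains with
an ensemble of genetic-algorithm classifiers over sequence-profile
windows.

A residue pair (i, j) with sequence separation ≥ 24 is a long-range
contact when the C-alpha distance is ≤ 8 Å. Each pair is encoded from
per-residue 20-column sequence profiles through three sliding windows
(9 residues at i, 5 at the integer midpoint, 9 at j), giving a 460-dim
L1-normalized vector. A genetic algorithm evolves a remove/merge
feature transformation — a string over `{a, b, c}` where `a` drops a
feature and runs of identical `b`/`c` merge adjacent features — scored
by nearest-centroid agreement on the training labels. Class imbalance
is handled by partitioning the non-contact samples into disjoint
contact-sized subsets, training one classifier per subset, and
combining votes (any-positive by default) and centroid-distance scores
across the ensemble. Rankings are evaluated with top-L/k accuracy
(2L, L, L/2, L/5, L/10, L/20) and accuracy/coverage.

## Layout

| module | role |
| --- | --- |
| `gacontact.profile_io` | PDB C-alpha traces, profile tables, RR files, model serialization |
| `gacontact.contacts` | contact maps, long-range pair enumeration and labelling |
| `gacontact.features` | pair encodings, class profile centers, dataset statistics |
| `gacontact.ga_transform` | chromosome grammar, centroid fitness, evolutionary loop |
| `gacontact.ensemble` | negative partitioning, classifier training, voting, cross-validation |
| `gacontact.evaluation` | confusion counts, Acc/Cov, top-L/k reports |
| `gacontact.synthetic` | geometry-derived synthetic chains and planted GA test sets |
| `gacontact.cli` | `gacontact simulate / train / predict / evaluate` |

## CLI

```sh
# generate a synthetic dataset (PDB + profile TSV + truth contacts)
gacontact simulate --out data/ --n-chains 10 --seed 1

# train an ensemble (reduced settings shown; defaults are
# population 150, stall 120, 20 classifiers)
gacontact train --data data/ --out runs/model.json \
    --n-gacs 5 --population 30 --stall 10 --max-generations 50 --seed 1

# rank all long-range pairs of each chain into CASP RR files
gacontact predict --model runs/model.json --data data/ --out runs/pred --seed 1

# score RR files (ours or an external predictor's) against truth geometry
gacontact evaluate --rr runs/pred/syn000.rr --data data/ --out runs/eval \
    --fractions 2,1,0.5,0.2,0.1,0.05
```

Every command takes `--seed`, is fully deterministic under it, writes a
JSON run manifest next to its outputs, and logs only to stderr.

Input formats: PDB `ATOM` records (C-alpha consumed, chain `A` by file
convention for datasets on disk); profile tables are whitespace-
delimited with header `idx aa A R N D C Q E G H I L K M F P S T W Y V`
(any column order accepted); predictions use CASP RR lines
`i j 0 8 p` with higher `p` = more confident.

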