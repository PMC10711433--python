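# selexg4

Analysis toolkit for SELEX (Systematic Evolution of Ligands by
EXponential enrichment) high-throughput-sequencing experiments, built
around the workflow that identified the preference of the forkhead
transcription factor FOXL2 for G₂-rich, G-quadruplex-forming RNA:

* **Read processing** — FASTQ parsing, the all-bases Phred filter
  (every base must satisfy Q ≥ 30, i.e. error probability
  P = 10^(−Q/10) ≤ 0.001), and recovery of the variable region between
  the fixed primer flanks of the library design.
* **Round enrichment** — per-round sequence counting and frequencies,
  detection thresholds (strict >0.003% / >0.005%, the latter being 50
  copies per million), nucleotide-composition evolution, and k-mer
  enrichment with frequency-weighted sequence logos (PWMs, MEME
  minimal format).
* **Family clustering** — greedy abundance-seeded clustering at a
  Levenshtein distance threshold (default 10), family abundance
  trajectories, and abundance-weighted family consensus logos.
* **G-quadruplex motifs** — G-doublet counting, QGRS-style candidate
  enumeration (four G-runs within 30 nt) with an integer G-score, and
  a matcher for the relaxed consensus
  G₂N₁₋₄G₂N₁₋₃G₂N₁₋₃G₂AN₁₋₂G₂AU₀₋₁G₂N₁₋₃G₂AN₀₋₂G₂.
* **Competition statistics** — per-replicate fold enrichment
  FE = count(RF00x)/count(scr50), with exact two-tailed Mann–Whitney U
  (full enumeration for n₁+n₂ ≤ 12) and Student's t tests.
* **Gene-list overlap** — hypergeometric upper tail P(X ≥ k) computed
  in log space, with the representation factor k/(n₁n₂/N).
* **Synthetic SELEX** — a fully seeded simulator of the selection
  (Bernoulli retention with a planted selection advantage s, then
  resampling amplification, so a planted family follows
  f′ = s·f/(s·f + 1 − f)), Phred-scored sequencing with substitution
  errors, competition mixtures with known retention ratios, and gene
  universes with planted overlaps — every analysis stage is
  exercisable without any external download.

The reference aptamer sequences of the study (RF000, RF001, RF002,
RF004, the scrambled control scr50 and the composition-preserving
mutant mutRF001) and both library designs ship in `selexg4.aptamers`.

## Worked example

```python
>>> from selexg4 import G2_CONSENSUS, RF001, SCR50, count_g_doublets, max_g_score
>>> count_g_doublets(G2_CONSENSUS)   # eight G doublets in the consensus
8
>>> max_g_score(G2_CONSENSUS)        # best quadruplex candidate scores 21
21
>>> max_g_score(RF001), max_g_score(SCR50)  # aptamer vs scrambled control
(24, None)
```

The numbered scripts under `analysis/` run the full study on synthetic
data and narrate what they find. For example
`python analysis/01_simulate_selex.py` followed by
`python analysis/02_enrichment_pipeline.py` prints, for a six-round
selection with one planted G₂-rich family (advantage 10, initial
frequency 10⁻³, 100 000 reads/round, seed 1):

```
round  pool_fraction  families>thr  %G
    0         0.0527           144   25.0
    1         0.9057          4946   25.1
    ...
    6         0.9953             6   39.9
top family seed has 9 G doublets and max G-score 22
```

i.e. the detected pool fraction rises monotonically, the number of
families above threshold collapses as a few families take over, the
average G content climbs from the unbiased 25% to ~40%, and the
winning family is the planted G₂-rich one.
`analysis/03_g4_aptamers.py` reproduces the aptamer dichotomy (all
four RF aptamers form quadruplex candidates and contain a consensus
match; scr50 and mutRF001 form none), `04_competition.py` the
fold-enrichment statistics, and `05_gene_overlap.py` the overlap test
(360- and 3381-gene lists sharing 114 genes in a 20 000-gene universe:
representation factor 1.87, P = 3.1e−12).

There is also a CLI (`selexg4 simulate|trim|count|detect|families|
kmers|logo|g4scan|compete|overlap|run`) whose subcommands wrap the
same library functions with files as the interface.

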