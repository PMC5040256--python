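# taxovote

Weighted-voting consensus taxonomic classification of metagenomic reads.

Shotgun-metagenomics classifiers disagree: similarity-search tools (BLAST-style)
call nearly every read but accumulate false positives, k-mer tools are precise
but abstain more, and marker-gene tools only see reads hitting their curated
databases. `taxovote` merges the per-read annotations of N such tools into a
single consensus taxon and confidence score per read, then turns the decisions
into per-rank abundance profiles and evaluation reports. It is aimed at
microbiome researchers who already run several classifiers and want one
defensible call per read without running anything new: the input is just a CSV
of each tool's taxon per read.

## The decision scheme

All voting happens on a simplified taxonomy backbone containing only the root
and the seven standard ranks (superkingdom, phylum, class, order, family,
genus, species); classifier output at strain or other non-standard ranks is
first lifted to its nearest standard-rank ancestor. For each read with
C ≥ 1 nonzero votes (out of N tools; a vote of 0 means "that tool did not
classify the read"):

1. Build a weighted tree: each backbone node's weight is the number of votes
   whose lineage passes through it, so weight(root) = C.
2. Among nodes with weight > ⌊C/2⌋, pick the node maximizing the summed
   weight along its root-to-node path; if several tie at the maximum, take
   the lowest common ancestor (LCA) of all tied nodes.
3. Report A = weight of the chosen node (the number of supporting tools,
   N ≥ C ≥ A) and the confidence score

       score = A/N                 if A = C
       score = A/N − 1/(m·N)       if A < C,  m > 1 (default 2)

   which always satisfies (A−1)/N < score ≤ A/N; with m = 2 a contested
   decision scores exactly mid-way between (A−1)/N and A/N. A read no tool
   classified gets taxon 0 with score 1 and A reported as N.

Abundance profiles at each rank count reads cumulatively over clades
(a species call supports its genus, family, …), normalized either by all
reads (genomic-based, n_x/n, the default) or by classified reads only
(marker-based, n_x/n_c). Evaluation against a read-level truth table reports
per-rank sensitivity TP_l/P_l, precision TP_l/(TP_l+FP_l), and the Hellinger
distance H = √(Σ_x (√P_x − √T_x)²/2) between predicted and true profiles.

## Worked example

Simulate a three-tool study (one sensitive-but-noisy similarity-like tool,
two precise-but-conservative k-mer-like tools) over a toy taxonomy, classify,
and score against the simulated truth:

```
$ taxovote simulate -o demo --seed 7 --reads 1000
$ taxovote classify -i demo/votes.csv -d demo/taxonomy -p demo/run
INFO taxovote: reads: 1000
INFO taxovote: reads no tool classified (C=0): 1
INFO taxovote: reads decided at root: 0
INFO taxovote: wrote demo/run_decisions.tsv and demo/run_profile.tsv

$ head -5 demo/run_decisions.tsv
read_id	C	A	score	taxon
read0001	3	3	1.000000	146
read0002	3	3	1.000000	182
read0003	3	3	1.000000	184
read0004	3	2	0.500000	120
```

`read0004` was classified by all three tools (C=3) but only two agreed with
the consensus (A=2), so its score is 2/3 − 1/6 = 0.5 — penalized, but still
above the (A−1)/N = 1/3 floor. Unanimous reads score 1.0.

```
$ taxovote evaluate -i demo/run_decisions.tsv -d demo/taxonomy \
    -t demo/truth.tsv -o demo/report.tsv
$ cat demo/report.tsv
level	P	TP	FP	sensitivity	precision	hellinger_genomic	hellinger_marker
superkingdom	1000	999	0	0.999000	1.000000	0.000503	0.000358
phylum	1000	999	0	0.999000	1.000000	0.000712	0.000618
class	1000	999	0	0.999000	1.000000	0.000950	0.000882
order	1000	999	0	0.999000	1.000000	0.000950	0.000882
family	1000	999	0	0.999000	1.000000	0.001351	0.001304
genus	1000	981	1	0.981000	0.998982	0.011619	0.011432
species	1000	925	3	0.925000	0.996767	0.055415	0.055267
```

The consensus is nearly perfect at shallow ranks and stays highly precise at
species level (3 false positives in 1000 reads): most single-tool errors are
outvoted or retreat to a safe ancestor, which costs sensitivity (92.5%) rather
than precision. `--min-support 2` suppresses single-tool decisions for an even
more conservative profile.

The library mirrors the CLI: `load_taxonomy`/`simplify`/`lift_to_standard`,
`read_votes_csv` plus Kraken/BLAST adapters, `decide_all`, `apply_min_support`,
`profile`, `evaluate_decisions`, and `make_dataset` for synthetic studies.

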