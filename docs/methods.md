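# Methods

This note documents the models, parameters and design choices behind
`ampedit`. It states no empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Scope and data model

The pipeline starts from *merged* amplicon reads (read merging, quality
trimming and chimera removal are upstream concerns) and a panel of
wild-type reference amplicons for one gene family. A dereplicated unique
read sequence with its count is an **Amp**; every statistic downstream is
weighted by these counts ("abundance"). Coordinates are 0-based half-open
on the forward strand throughout; reports convert to presentation form
(one decimal place for percentages) only at the formatting layer.

## Dereplication and family screening

Denoising is approximated by a minimum-abundance filter
(`min_count`, default 2): genuinely edited molecules are sampled
repeatedly, while stochastic error sequences are mostly singletons. The
default suits real data with sequencing error; analyses that must conserve
every read (e.g. planted-truth validation) pass `min_count=1` explicitly.
FASTQ qualities are parsed but ignored unless the optional mean-Q filter is
enabled (default off), since quality control belongs to the merge stage.

Family membership uses k-mer containment: an Amp is kept when at least
`min_shared_frac` (default 0.5) of its k-mers (k = 12) occur anywhere in
the panel. The defaults are chosen so that an amplicon carrying a full
129-bp excision — which loses only the k−1 junction-spanning k-mers plus
the excised block's — passes comfortably, while unrelated sequences share
essentially no 12-mers and are discarded.

## Guide sites and cut windows

A *primary* site requires an exact PAM (IUPAC pattern; NGG for Cas9, TTTV
for Cas12a) and an exact PAM-proximal seed (default 12 nt); mismatches in
the PAM-distal remainder are counted but tolerated, which is how family
members diverging from the designed target still register as binding
sites. *Degenerate* sites allow up to 3 total mismatches anywhere and are
flagged; the degenerate list always contains the primary list, which
requires treating perfect-seed sites as degenerate-eligible regardless of
their distal mismatch count.

Cut models: Cas9 cuts bluntly 3 nt 5′ of the PAM, with evidence for an
occasional 1-nt 5′ overhang — the attribution window is
`[cut−1−pad, cut+pad)` (pad default 5 nt, mirrored on the minus strand).
Cas12a cuts 18 nt (non-target strand) and 23 nt (target strand) 3′ of the
PAM; the window spans both cuts ± pad, and the non-target-strand cut is
the single `expected_cut` used for excision bookkeeping. The pad absorbs
imprecise InDel placement in repetitive sequence before normalization.

## Alignment

Both aligners are affine-gap Gotoh DP over full matrices with stored
choice matrices, so traceback is deterministic: diagonal over deletion
over insertion, gap closure over extension at equal score. An insertion
gap never re-opens directly from an insertion state; with a positive gap
open this excludes no optimal path and keeps the row recurrence
single-pass. The inner fill is a numba kernel; a naive pure-Python
full-matrix oracle in the test-suite checks score, op-path and endpoint
identity on random pairs for both modes.

* **local** (default `match +2, mismatch −3, open −6, extend −1`):
  Smith–Waterman; unaligned query ends are clipping, and terminal gap ops
  are never events.
* **global** (`match +2, mismatch −3, open −25, extend −0.1`, implemented
  ×10 integer-scaled): Needleman–Wunsch with free end gaps on the
  reference side (the query is consumed in full). The near-free extension
  makes one long deletion cheap; the stiff open keeps it in one piece
  instead of threading through the chance 1-in-4 matches any two unrelated
  DNA segments share.

Closest-reference choice preselects the top 8 candidates by shared-k-mer
count, takes the best local alignment (ties: score, then baseline
abundance, then lexicographic id), and escalates to global alignment when
clipping exceeds 15% of the query — the signature of a large deletion that
local alignment truncates — keeping the global result when its full-query
identity is higher. Amps sharing no k-mer with the panel are flagged
unalignable and excluded from all denominators.

## Event extraction and normalization

Interior I/D runs become events (signed length negative for deletions);
substitutions never do. Two refinements reduce false negatives in
repetitive and replaced sequence:

1. **Gap consolidation**: gap ops separated by aligned runs of ≤ 8 columns
   are folded into one deletion plus one insertion. A replacement junction
   almost never aligns as a clean D + I because chance matches bridge the
   gaps; consolidation restores the canonical pair without changing the
   query/reference correspondence.
2. **Cut-window normalization**: each event is re-placed within its
   repeat-equivalence class (all placements producing the same edited
   haplotype, enumerated exactly) to maximize total cut-window overlap,
   ties breaking leftward; with no overlapping placement this is plain
   left-alignment. Normalization is idempotent and haplotype-preserving.

## Classification and statistics

An event is assigned to every guide whose window it hits (deletions by
interval overlap, insertions by point membership, window edges inclusive).
A **multi-guide excision** is one deletion covering ≥ 2 expected cuts;
coverage allows `tol` = pad bases of slack because a chance match can
steal a column or two from a gap edge at a replacement junction. Frame
status is the net signed length of *all* events on the Amp modulo 3.

Sample statistics are abundance shares of the family: `editing_pct` counts
Amps with ≥ 1 assigned event once; deletion/insertion percentages count
carriers of each kind (an Amp can be in both, so their sum may exceed the
editing percentage — the editing bounds
`max(del, ins) ≤ editing ≤ del + ins` hold by construction). Per-guide
efficiency divides by the abundance of Amps whose chosen reference carries
a *perfect-seed* site for that guide: degenerate-site edits count toward
editing but not toward designed-target efficiency. The InDel spectrum is
the abundance-weighted share of each signed length among assigned events;
it sums to 100 and the 0.5% display threshold is applied only when
formatting reports. Excision frequency per Alpha type requires the
excision span to cover the reference's annotated epitope-coding interval
(within tol). Amps mapping to references without guide sites are
wild-type unless they carry an unassigned InDel, which is reported
separately and excluded from editing percentages.

## dsODN detection

Insertions are tested against both strands of each dsODN design with local
alignment; a call needs identity ≥ 0.9 over ≥ 0.8 of the dsODN and an
insertion point inside a cut window (thresholds configurable — junctions
are often imperfect, and no single cutoff is canonical). Orientation is
the better-matching strand; the scenario is `replacement` when the Amp
also carries a paired-cut excision, else `single_cut`.

When the replacement and the replaced fragment have comparable lengths,
the optimal alignment is a mosaic with no single insertion event. The
detector then reconstructs the query segment aligned opposite the
inter-cut reference span, requires its length to be within
`[0.8, 1/0.8] ×` the dsODN length (a genuine replacement leaves little
residual block sequence), and tests it against the dsODN strands; on a hit
the mosaic events inside the span are rewritten as the canonical
cut-to-cut deletion plus insertion — an exact re-representation of the
same read sequence. Events crossing the span boundary abort the rewrite.

dsODN orientation frequency divides the abundance-weighted dsODN calls by
**all** insertion events, targeted and non-targeted.

## Epitope profiling and relative loss

Scanning counts motif occurrences at every offset (overlaps allowed) in
the translation of the reference's annotated frame, carried onto each Amp
through its alignment offset; frameshifted Amps lose downstream motifs by
construction, and substitution-broken motifs count as lost because loss is
computed by re-scanning, not by coordinate bookkeeping. The Alpha type is
the total DQ2.5 hit count capped at 7 (Alpha0 = no epitopes, Alpha7 = the
complete 33-mer + α3); an internal stop codon overrides the count and
marks a pseudogene. The p31-43 innate-immunity peptide is configurable,
tracked separately, and never enters the type count.

Relative loss of motif *e*:

```
loss(e) = 100 · Σ_r b(r) · E_amps→r[ (hits_e(r) − hits_e(amp))⁺ / hits_e(r) ]
               ───────────────────────────────────────────────────────────
                      Σ_{r : hits_e(r) ≥ 1} b(r)
```

with `b(r)` the baseline abundance of reference *r* and the inner
expectation abundance-weighted over the Amps assigned to *r*. Losing every
copy of *e* on every epitope-bearing amplicon gives exactly 100% per
motif; partial copy loss counts proportionally. The combined loss sums the
per-motif losses (plus p31-43 when tracked) and therefore exceeds 100%
when several motifs are lost together — deliberately, since each motif's
loss is already normalized to its own carriers. This formula is one of
several defensible abundance-weighted definitions; it was chosen because
it is exact at the two calibration points above and monotone in the
edited fraction.

## Synthetic data generator

The generator emulates a tandem gene family of eight archetypes
(Alpha0–Alpha7) plus optional pseudogenes. Each reference is
`[PRE 72 nt][CCA GCA][excised span][GTC TGG][POST 72 nt]`, frame 0, with
the upstream guide on the minus strand (PAM `CCA`→`TGG` outside the span)
and the downstream guide on the plus strand; the excised span codes
`LQLQPF + (PQPQLPY)×r + PQPQPF + {F|S}RPQQPYPQ + P`, giving 2r DQ2.5 hits
plus one when the tail F completes α3 — so r = 3 with an F tail is the
Alpha7 archetype, 43 codons = 129 bp cut to cut, and its excision is
in-frame and removes the complete 33-mer + α3. The upstream guide must sit
on the minus strand: the 126-bp epitope block leaves only 3 bp of slack
inside a 129-bp excision, with no room for a PAM. Guide footprints and
PAMs are fixed constants across references; every other codon (flanks and
epitope-block middle) is wobble-randomized per reference, so family
members are distinguishable both inside and outside the excised span, and
an edited read's closest reference is its true source. Flank residues
exclude Y and R, so no DQ2.5 motif (each needs a Y or R) can arise outside
the designed block. Panels are self-checked at build time: the translation
of each reference carries exactly the requested hit count and each guide
has exactly one perfect-seed site at the designed cut.

Baseline abundances are Dirichlet draws with per-reference concentration
`conc(type)/n_type`, `conc = {Alpha0: 30, …, Alpha7: 2, pseudogene: 15}` —
the qualitative wild-type skew (Alpha0 most abundant, Alpha7 rare). The
default editing spec: per-guide InDel probability 0.15; signed-length
distribution peaked at −36 bp within −45…+9 (inside the broader −141…+49
range such experiments produce, but capped so a single-guide deletion can
never span both cuts of the smallest archetype); excision probabilities
{Alpha7: 0.20, Alpha5: 0.05, Alpha3: 0.02, Alpha1: 0.01}; dsODN capture
probability 0.05 conditional on an editing outcome, orientation (0.8,
0.2) forward-biased; substitution error 0.002/base, matching post-merge
error levels. Excisions delete exactly cut-to-cut; single-guide deletions
are centered on the expected cut; insertions carry random bases; errors
are applied last. The truth table records, per read, the source
reference, planted events with guide attribution (computed with the same
cut-window geometry the classifier uses), category, excision flag and
dsODN orientation.

The default simulated dsODN is a **synthetic** epitope-free in-frame
cassette whose codon content is deliberately dissimilar from the P/Q-rich
epitope block: P/Q-rich DNA is self-similar at the codon level
(CCN/CAN), and a gliadin-like cassette would make every replacement
junction align as an irrecoverable mosaic. Real dsODN sequences can be
supplied in the run config.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: PCR chimeras and polymerase slippage, quality-
score-correlated errors, indel sequencing errors, paired-end artifacts,
primer-site variation, and genuine biological haplotype diversity beyond
codon wobble. Planted-truth recovery demonstrates the calling logic is
exact given correct alignment, not that real-world noise modes are
handled.

## Problem sizes and numerical choices

Validation runs use a 12-reference panel of ~220–290 bp amplicons and
10,000 reads — comparable amplicon lengths to the real assay with a
scaled-down panel and read count, keeping the full suite in minutes while
leaving every code path exercised. Integer scoring avoids floating-point
ties; all randomness flows from explicit seeds (panel construction, read
simulation and the test-suite are seeded; reruns are byte-identical).
Degenerate inputs are defined: empty read sets dereplicate to an empty
AmpSet; zero family abundance reports NA statistics; zero insertions make
dsODN frequencies NA; an epitope absent from the panel reports NA loss.

## Known limitations

* Excision calling requires one spanning deletion; two independent
  deletions that jointly remove the region are reported as single-guide
  edits (deliberate, matching the paired-cut mechanism).
* The replacement rewrite tests only the outermost cut pair; nested
  partial replacements between adjacent guides of a 3-guide design fall
  back to insertion-event detection.
* Whether editing denominators should include family members bearing no
  guide sites is a reporting convention; this package includes them.
* The synthetic panel builder constructs Cas9 layouts; Cas12a site
  scanning and windows are fully supported and fixture-tested, but no
  Cas12a archetype builder is provided.
* Alignment is exact DP (no banding); amplicons far above ~1 kb would need
  banding or seeding for throughput.
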