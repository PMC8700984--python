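# Methods

`conchicore` implements, end to end, the desk-scale analysis by which shell
matrix proteins (SMPs) are identified from a mollusk's own transcriptome and
shell proteome, compared across five conchiferan species, and projected back
onto the ancestral conchiferan. This note records the models, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical conventions.

## Identification model

**ORF calling.** Transcriptome contigs from shallow sequencing are short and
mostly partial CDS, so ORFs are called as maximal stop-free stretches in all
six reading frames (open-ended mode), with a `require_met` flag for
Met-initiated calling. The length cutoff defaults to >= 100 residues,
inclusive; the strict "longer than 100" reading is available by passing 101.
Codons containing N translate to X, and X-containing peptides are dropped
from the search space with a warning, so ambiguous sequence can never
support an identification.

**In-silico digestion and matching.** Proteins are digested with the trypsin
rule (cleave after K/R, not before P), enumerating peptides with up to 2
missed cleavages and length 6-50. Theoretical spectra are singly charged b/y
ladders from fixed monoisotopic residue masses; no PTMs, no isotope
envelopes. A spectrum is matched only against peptides whose neutral mass
lies within 10 ppm of its precursor; the score is the *matched-ion
fraction* — the share of theoretical b/y ions found within 0.5 Da — which is
deterministic and exactly checkable against hand enumeration, unlike a
cross-correlation score. Ties break toward fewer missed cleavages, then the
lexicographically smaller sequence. PSMs scoring below `min_score = 0.4` are
discarded.

**Protein inference.** Confident PSMs are grouped by contig. A contig
becomes an accepted SMP when it is supported by at least two *distinct
peptide sequences* (a `count_spectra` flag switches to spectrum counting) in
exactly one reading frame. Contigs with confident matches in two or more
frames are flagged as likely frameshift artifacts and excluded from the
comparative stage; the flag deliberately considers confident PSMs only, so a
single noisy sub-threshold match cannot disqualify a contig.

## Cross-species comparison

Pairwise protein comparison uses Smith-Waterman local alignment (BLOSUM62;
a gap of length k costs 11 + k). E-values come from the Karlin-Altschul
formula E = K m n e^(-lambda S) with fixed gapped-BLOSUM62 constants
(lambda = 0.267, K = 0.041) — a declared calibration, not a fitted one, and
n is the total residue count of the searched species' set. Two stringency
settings gate hits: Setting 1 (E < 1e-5 and >= 50% identity over aligned
columns, gap columns included) and Setting 2 (E < 1e-5 alone). The >= 50%
threshold is interpreted as percent identity (a coverage interpretation is
a config flag). A focal protein is *present* in another species when some
subject passes the setting forward and that subject's best hit back into
the focal set also passes (reciprocal hit-above-threshold; strict
reciprocal-best-hit is behind `strict_rbh`). Presence-matrix rows partition
into: shared by all five species; shared by the four marine species only;
shared with exactly one other species; focal-specific; other.

## Domains and signal peptides

Domain presence uses bundled synthetic mini-profiles: one position weight
matrix per domain family, built around a fixed consensus motif (consensus
residue probability 0.70, remainder uniform), scored as log2 odds against a
uniform background. Thresholds sit at half the consensus score and are
verified by a seeded calibration — 10,000 random 300-residue protein scans
per profile with zero above-threshold windows, i.e. a false-positive rate
below 1 per 10^4 scans (`scripts/build_domain_profiles.py`). These profiles
capture the presence/absence set logic of the comparison; they are not
substitutes for curated HMMs, and real-data domain coordinates should not
be read off them. Overlapping same-domain windows merge to the best-scoring
one.

Signal peptides are called by a tripartite heuristic: >= 1 K/R in residues
1-5; a 7-residue window in residues 6-20 with mean Kyte-Doolittle
hydropathy >= 2.0; and small residues (A/G/S/C) at -3/-1 of the
best-scoring cleavage position in [10, 35]. The heuristic is monotone in
h-region hydropathy. A positive call is recorded as a "Signal Peptide"
domain feature, since the species comparison treats it as one.

## Ancestral reconstruction and gene trees

The species tree is fixed:
`(Nautilus,((Lottia,Euhadra),(Crassostrea,Pinctada)))`, rooted between
Nautilus and the rest. Ancestral domain presence uses Dollo parsimony — at
most one gain per domain, losses free — as the explicit model behind the
"ancestral conchiferan" domain set: the gain sits on the edge above the
MRCA of the present leaves, nodes inside that clade are present unless all
their descendant leaves are absent, and the root is present iff the gain is
on the root edge. Exhaustive enumeration over all 32 leaf patterns confirms
the reconstruction is the unique loss-minimizing single-gain assignment.
Unweighted Fitch parsimony is available as an alternative
(`fitch_ancestral`).

Gene trees for the monophyly question are neighbor-joining trees on
Poisson-corrected distances d = -ln(1 - p·20/19), with p from pairwise
local alignments (or column mismatches for pre-aligned input) and a cap of
d = 10 when p >= 19/20. Monophyly of a tip subset is assessed on the
unrooted tree: true iff some edge bipartition separates exactly that
subset. ML inference, alignment trimming and bootstrap are deliberately out
of scope; the reproducible claim is the topological statement, not branch
support.

## Synthetic data: what it emulates, and what it does not

The generator plants every structure the pipeline is supposed to recover,
with defaults chosen to mirror the study conditions at desk scale:

| parameter | default | role |
|---|---|---|
| `n_smp_proteins` | 60 | planted SMPs in the focal transcriptome |
| `frac_frameshift` | 14/61 | fraction of SMP contigs with a 1-nt indel |
| `spectra_per_smp` | 3 | distinct-peptide spectra per true SMP |
| `core_structure` | {3 all, 5 marine, 2 pair} | planted conservation classes |
| `homolog_identity` | 0.70 | target identity of cross-species homologs |
| `fragment_dropout` / `noise_peak_rate` | 0.1 / 0.1 | spectrum degradation |
| `protein_len_range` | 240-320 aa | SMP length |
| `n_decoy_contigs` | 40 | non-SMP contigs |

Contigs are back-translated with uniform codon choice, padded with random
UTR (0-150 bp, codon-aligned with a stop codon flanking the CDS on both
sides so the encoding frame's stop-delimited ORF is exactly the planted
protein) plus a 0-2 nt phase offset so the CDS lands in any forward frame.
Frameshift contigs carry one inserted nucleotide at a codon boundary at
least 110 codons from either CDS end, so both flanking ORFs clear the
100-residue cutoff; their spectra draw peptides from both sides of the
indel, which is what makes the multi-frame exclusion observable.
Frameshifts are assigned within the focal-specific class only, so the
planted cross-species core structure survives the exclusion intact and the
recovery check on core-set classification is well-posed. Homologs are
derived from the focal sequence by i.i.d. substitutions toward
BLOSUM62-favored residues (no indels by default); planted domain motifs and
the signal-peptide prefix are excluded from mutation, treating domains as
strongly conserved islands.

Limitations to keep in mind: proteins are longer (240-320 aa vs a real
average contig of a few hundred bp) because both halves of a frameshifted
CDS must host a >= 100 aa ORF; spectra are clean b/y ladders with uniform
intensities, so passing tests demonstrate the correctness of the matching
logic, not robustness to real fragmentation chemistry; homolog divergence
has no indels or rate variation; and domain detection on mutated homologs
succeeds by construction (conserved motifs), so it validates the set logic
rather than remote-homology sensitivity. Counts at the defaults:
60 = 46 accepted + 14 excluded, mirroring the identified/accepted/excluded
bookkeeping structure of the study it emulates.

## Numerical conventions

Coordinates are 0-based half-open everywhere internally. Masses use
monoisotopic residue values with water 18.010565 Da and proton 1.007276 Da.
Alignment ties break toward the lexicographically smallest subject id. The
e-value of a zero-score alignment is infinite. All randomness flows from a
single `numpy` Generator seeded by `SimConfig.seed`; identical seeds give
byte-identical datasets. Problem sizes in the tests and the acceptance
script (60 SMPs, 100 contigs, 180 spectra, 200-case oracle comparisons)
are the package's chosen desk-scale defaults; the whole suite runs in well
under a minute apart from the end-to-end run (~7 s).
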