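# Methods

## Locus model

The β-globin gene is modelled on its sense strand as a single ~1 kb
amplicon: three exons, a 444 nt CDS (147 residues plus the natural stop),
and two introns with canonical GT/AG boundaries. Internally all
coordinates are 0-based half-open; every rendered HGVS coordinate is
1-based. Coding positions are numbered c.1 from the A of the initiator
ATG; intronic positions are rendered relative to the nearest exon
boundary (`c.92+1` is the first base of intron 1), with the first half of
an intron numbered from the upstream exon and the second half from the
downstream exon. UTRs and the other genes of the extended β-globin
cluster are not modelled: every lesion the pipeline targets lies in the
*HBB* coding region or its splice sites.

The bundled reference (`hbb_synthetic.fasta`) is a **synthetic** HBB-like
sequence, not a database accession. It is constructed so that every
clinically pinned feature of real *HBB* holds exactly: codon 1 = ATG,
codon 3 = CAT (His3), codon 7 = GAG (the sickle codon, so c.20A>T →
Glu7Val), codon 23 = GAG, codon 38 = TGG, codon 40 = CAG, codon 60 = AAG,
a 147-residue protein, exon 1 coding span c.1–c.92, and no premature stop
codons in the reference frame. All other codons are arbitrary. This keeps
the repository download-free while making every variant name, consequence
and truncation fraction behave exactly as on the real gene. Consequences
of the design: coordinates are locus-relative (not chromosomal), and
alignments of real *HBB* reads against this fixture would be meaningless
— users genotyping real data must supply their own reference FASTA and
transcript spec.

## Annotation

Coding substitutions are translated with the standard genetic code;
protein numbering follows current HGVS (initiator Met = residue 1, so the
sickle variant is Glu7Val), with the legacy mature-chain name (Glu6Val)
emitted as an alias. Stop gains are rendered with `X` (Trp38X) rather
than `Ter`. Splice annotation is limited to intron offsets ±1/±2; deeper
intronic substitutions are `intronic`. Donor-site lesions get an
`IVSn-k` legacy alias. A stop at codon *k* of an *L*-residue protein
truncates `(L − (k − 1))/L` of the coding region — Trp38X on the
147-residue protein removes ≈ 75 %.

## Allele catalogue

Each catalogued allele carries a clinical class: `beta_S` (the sickle
allele), `beta_zero` (no β-globin: stop-gains), `beta_plus` (reduced
β-globin), or `benign`. Two placements follow the clinical labels of the
assay's evaluation cohorts rather than the classical molecular
expectation, and are therefore explicit and configurable rather than
silent:

* the IVS1-1 splice-donor lesions (c.92+1G>A/T) default to `beta_plus`
  as clinically reported, although splice-donor destruction classically
  yields a β⁰ phenotype; `default_catalog(ivs1_as_beta_zero=True)`
  switches them;
* the start-loss c.2T>C (Met1Thr) is kept `beta_plus` per its clinical
  reporting, although start-loss is classically β⁰.

Variants absent from the catalogue are classified by predicted
consequence: stop-gain/start-loss/±1,2-splice → `beta_zero` candidate
flagged uncatalogued; synonymous/intronic → `benign`; missense → `VUS`,
which always routes the sample to review.

## Read simulator

The simulator emulates multiplexed amplicon sequencing of the locus.
Each read is drawn from a uniformly chosen haplotype and strand, spans
the full locus by default (a `read_fraction` option generates partial
reads for testing phasing degradation), carries its sample barcode as a
prefix, and is corrupted by i.i.d. errors. Defaults: substitution rate
0.02, insertion 0.005, deletion 0.005, per-base Phred qualities drawn
from a clipped normal around Q20 (sd 5, range 2–41). The error
decomposition is a design choice calibrated to an aggregate quality of
roughly Q20; it is substitution-dominant so the pileup caller and its
quality filter are honestly exercised without overwhelming indel
handling. Qualities are drawn independently of whether a base is an
error, so the Q15 filter removes a representative ~16 % of bases rather
than preferentially removing errors — a conservative choice that makes
the depth filter bite realistically.

What the simulator does **not** emulate: homopolymer-biased nanopore
errors, quality–error correlation, chimeric or adapter-contaminated
reads, coverage bias, and large deletional thalassaemias. Passing tests
therefore demonstrate the pipeline's logic under a clean i.i.d. error
model at realistic rates, not robustness to every nanopore artefact.

Determinism: each per-sample configuration carries a seed; a fixed seed
reproduces the FASTQ byte-for-byte (numpy `default_rng` with explicit
per-sample seeds derived as `seed·1000003 + i·7919 mod 2³¹`).

## Demultiplexing and alignment

The bundled whitelist holds 24 sixteen-base barcodes with pairwise edit
distance ≥ 7. A read is assigned when exactly one whitelist barcode (in
either orientation) matches within edit distance 2 of the read's first
`barcode length + 10` bases; ties and misses go to an unassigned bin, and
the matched prefix is trimmed. Assigned + unassigned always equals the
input read count.

Alignment is pairwise semi-global (free gaps at the reference ends, the
read fully consumed) against the single locus — a general-purpose mapper
is unnecessary for a one-amplicon assay. Two backends share one
interface: the default uses edlib's bit-parallel alignment with a full
path (unit edit costs), and a self-contained affine-gap Gotoh aligner
(match +2, mismatch −4, gap open −4, gap extend −2, vectorised over the
query axis) serves as an alternative backend and as an independent
cross-check in tests. At the error rates of interest the two produce the
same mismatch columns at variant sites. Reads shorter than 200 bases or
aligning below 70 % identity are rejected (counted, not erroneous); both
strands are tried and reads are reoriented to the reference strand before
any downstream use, making pileups strand-invariant by construction.

## Variant calling

Pileup columns count aligned bases with quality ≥ 15 (`depth_pass`);
deletions are tallied per column and insertions against their anchor
column, but indels are reported through a side channel and not genotyped
— every lesion in the assay's scope is a substitution. Per column the
strongest non-reference base with VAF ≥ 0.25 becomes a candidate:

| condition | zygosity | filter |
|---|---|---|
| depth_pass < 200 | by VAF | `low_depth` |
| VAF ∈ [0.40, 0.60] | het | `PASS` |
| VAF ≥ 0.75 | hom | `PASS` |
| otherwise | ambiguous | `ambiguous_vaf` |

Both het-window bounds and the hom threshold are inclusive. The
0.60–0.75 gap and the 0.25–0.40 floor are deliberately a reportable
ambiguous state: diagnostic software must not swallow borderline results.
The 0.25 noise floor reflects that long-read substitution artefacts sit
well below constitutional VAFs at the depths this assay runs. All
thresholds live in `CallerConfig`.

## Phasing

With full-locus reads, every read informative for a heterozygous pair
spans both sites, so pairwise majority counting is complete evidence and
a minimum-error-correction solver would add nothing. Reads contribute
only if they carry a quality ≥ 15 base at both sites that is either the
reference or the called alternate; others count as uninformative. A pair
is cis/trans when the concordant/discordant fraction of informative reads
reaches 0.8 with at least 20 informative reads, else unphased. The 0.8
and 20 are design choices set far from both the error regime (support at
depth ≥ 200 is ≈ 0.95+) and the decision boundary; unphased compound
pairs route to review rather than to a disease label.

## Interpretation

The cascade over PASS calls: no pathogenic allele → normal; βS hom →
sickle cell disease; lone βS het → sickle cell trait; one β-thal allele →
β-thal trait; two β-thal alleles → homozygous β-thalassaemia; βS het
plus β-thal het → compound heterozygote if trans, a single complex
cis allele if cis, review if unphased. Any ambiguous zygosity or
non-PASS filter on a non-benign allele, and any VUS, forces
`needs_review`; the engine cannot emit a definitive disease label from
uncertain input (property-tested by exhaustive enumeration of dosage ×
phase combinations). Concordance against external diagnosis labels uses
an explicit mapping table from engine labels to accepted printed
synonyms, with whitespace/case/superscript normalisation.

## Cost model

Consumable lines are `per_sample` (fixed units each), `per_library`
(amortised over the samples sharing one barcoded library), or
`per_flowcell` (the item's full price — per-reaction price × quoted
capacity — amortised over samples × libraries, reflecting that a flowcell
can be flushed and reused across libraries). At 24 samples/library and 8
libraries/flowcell the bundled seven-line table totals £11.56 per sample;
the assay's reported consumables price is £11.57, with the £0.01–0.02
gap attributable to intermediate per-line rounding in that reported
breakdown (whose own rounded lines sum to £11.58). The model computes
from unrounded fractions and documents a ±£0.02 presentation tolerance.
Per-sample cost is non-increasing in both multiplexing factors
(property-tested).

## Problem sizes in tests and the acceptance script

The pipeline-level checks simulate nine samples at depth 2000 (variant
recovery), three compound-het samples at depth 1000 over 20 seeds (phase
recovery), and smaller cohorts at depths 40–400 for unit-level
properties. These sizes put binomial VAF noise far inside the decision
windows (at depth ~1700 quality-passing, the het VAF standard error is
≈ 0.012) while keeping the whole suite fast; they are the package's
choice of demonstration scale, two orders of magnitude below the
instrument depths the assay reports, which changes nothing about the
decision logic being exercised.

## Known limitations

* Substitutions only: no indel, structural or large-deletion genotyping.
* Single-locus: no multi-gene panels, no α-globin, no HbC/HbE logic.
* The synthetic reference is for development and validation, not for
  aligning real reads.
* Phasing is pairwise; three-site haplotypes are reported pair-by-pair.
* The cost model covers consumables only — no labour, capital,
  shipping or maintenance.
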