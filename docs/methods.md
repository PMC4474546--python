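# Methods

## The document model

An RDML document is held as a plain dataclass tree mirroring the format's
top level — experimenters, documentations, dyes, samples, targets, thermal
cycling conditions, experiments — with experiments holding runs and runs
holding reactions. A reaction references one sample; each of its data
entries references one target and carries the observed Cq, baseline,
quantification threshold, and the raw amplification (cycle, fluorescence)
and melt (temperature, fluorescence) point lists. Construction never
validates cross-references: partially built or deliberately broken trees
are representable, and all integrity checking lives in the validator.
Reaction positions are always stored as 1-based row-major linear indices;
the well-label representation of version 1.0 files exists only at the I/O
boundary.

Two conventions deserve emphasis because files from other tools may differ:

* **Efficiency scale.** `amplificationEfficiency` (and its SE) is a
  fold-change per cycle — perfect doubling is 2.0, and the standard-curve
  relation is E = 10^(−1/slope). Values are never rescaled on read; a file
  storing percentages would read as-is and look implausible (> 2), which
  the fitting range documentation calls out rather than silently "fixing".
* **Sample-type vocabulary.** `unknown`, `standard`,
  `no-template-control`, `no-amplification-control`, `positive-control`,
  serialized as the short tokens `unkn/std/ntc/nac/pos`. Unrecognized
  tokens are kept verbatim so third-party files round-trip losslessly; the
  validator flags them as warnings, not errors.

`semantic_equal` is the round-trip oracle used throughout the tests: it
compares canonical forms in which every unordered list (top-level element
lists, runs, reactions, per-reaction data, annotations, opaque extras) is
sorted by its natural key, text is whitespace-normalized, and numbers are
compared to 1e−9 relative tolerance (1e−12 absolute floor). Genuinely
ordered sequences — cycling steps, curve points — keep their order.

## Container I/O

Files are zip archives with one XML member; the writer always names it
`rdml_data.xml`, the reader accepts any single `.xml` member (warning when
the canonical name is absent) and bare XML, reporting which form it saw.
Determinism is a contract: fixed zip metadata (epoch timestamp, fixed
permissions), stable element ordering, and shortest-round-trip decimal
formatting (`repr`) make writing the same document twice byte-identical —
useful for diffing and for the rewrite tests. Unknown elements anywhere in
the tree are kept as opaque serialized strings on their parent and
re-emitted verbatim, so vendor extensions survive read–write cycles. The
output is deliberately compact (no pretty-printing): re-indenting foreign
elements could change their serialization between writes.

Writing validates first and refuses on errors (a `force` flag overrides),
so a 1.1 document cannot silently acquire a 1.2-only annotation.

## Validation

Validation is rule-based over the in-memory model: the three version
dialects differ in a small number of explicit rules (mandatory dye
registration and numeric positions from 1.1; annotations, the unified
quantity and the efficiency-SE element only in 1.2), and encoding them
directly keeps one implementation for documents of any origin. An optional
hook cross-checks the serialized form against an external XSD when one is
available. Referential and structural breaches are errors; vocabulary
deviations and missing recommended metadata (an experimenter without an
email) are warnings — such files are valid but hard to use. A report with
no issues renders exactly `validation successful`; otherwise one line per
issue with severity, stable code, element path and message, in document
order (so validation is idempotent and diffable).

## Migration

Migration chains adjacent-version steps (1.0→1.2 passes through 1.1) and
returns a new document plus a report listing each applied step and one
action per changed element, classified `transformed` / `synthesized` /
`dropped`:

* **1.0→1.1** expands the predefined plate type into an explicit
  rows x columns format and switches reaction identification to numeric
  positions; every target without a dye gets one synthesized
  (`dye_<targetid>`, deduplicated with numeric suffixes — deterministic so
  migration is reproducible) because dye registration becomes mandatory.
* **1.1→1.2** re-houses material-specific quantities as the unified
  quantity element and converts legacy DNA/RNA quality records into
  annotations (`dna quality` / `rna quality`).
* **Downgrades** reverse each rule where possible: quality annotations are
  converted back into legacy records, quantities return to their
  material-specific slot (an unknown material goes to the DNA slot with an
  action noting the ambiguity), and everything not representable —
  ordinary annotations, the efficiency SE — is dropped with exactly one
  action each. Reducing a format to a 1.0 plate type uses reverse lookup
  in the plate map and fails loudly for geometries with no token.

Well numbering is row-major (position = (row−1)·columns + column, rows
lettered A..Z then AA, AB, …), matching the conventional reading order of
a plate; the conversion is centralized so a column-major dialect (some
rotor instruments) could be added behind a flag. The shipped plate map
covers 96-well (8x12), 384-well (16x24), 48-well (6x8), rotor-72 (72x1)
and rotor-100 (100x1); unknown tokens raise, carrying the token, and a
custom token→geometry map can be supplied, because a silently guessed
geometry corrupts every position on the plate.

## Plate views and export

All views are read-only — raw instrument readings should never be edited —
and the tests assert the document is unchanged after every export. CSV is
RFC 4180 (comma, CRLF, double-quote escaping) with `.` decimals and empty
fields (never `NaN`) for missing values; the long form is one row per
fluorescence point and re-imports to the exact stored point sets because
numbers are written with shortest-round-trip formatting. SVG charts are
standalone (style in attributes, no CSS), linearly scaled into a fixed
viewBox with 5% margins, one polyline per series, and byte-deterministic
for fixed input (coordinates rounded to 2 decimals).

## Efficiency estimation

The standard-curve route regresses Cq on log10(input) by ordinary least
squares (scipy's `linregress`) over all standard reactions of a target —
replicates enter as independent observations, preserving degrees of
freedom. log base 10 is fixed and documented, since the familiar "−3.32
per 10-fold" slope reading depends on it. The efficiency SE uses the
first-order delta method on E = 10^(−1/slope):

    SE(E) = E · ln(10) · SE(slope) / slope²

cross-checked in the tests against a 10,000-replicate parametric bootstrap
(known design, Gaussian Cq noise, SD 0.1): the two agree within 20% at
that noise level. Degenerate inputs (< 3 points, < 2 distinct input
levels, non-finite values) raise; a non-negative slope warns and returns,
since E ≤ 1 is diagnostically useful even if biologically meaningless.
The per-curve route — mean and SEM of externally computed per-reaction
efficiency values — consumes numbers produced by amplification-curve
analysis software; computing them is out of scope here, so the CLI takes
them as an explicit value list.

## The synthetic generator

The generator emulates what analysis software sees, not PCR chemistry:
a logistic sigmoid F(c) = Fb + Fmax/(1 + exp(−(c − cMid)/k)) with
Fb = 0.05, Fmax = 1.0, k = 1.2 cycles, cMid placed so the threshold
Fthr = 0.1 is crossed exactly at the reaction's true Cq; melt curves are a
decreasing sigmoid of width 1.5 °C at the product Tm. True Cq values
follow the dilution law trueCq = cqAtUnitInput − log10(input)/log10(E).
Defaults describe a routine singleplex assay: a 1.2 document on a 96-well
plate, one target at E = 1.9 with Cq 35 at unit input, a 5-step 10-fold
series starting at 1e5 copies in duplicate, two unknowns at 1e3 copies,
one no-template control (flat noise, no Cq), 40 cycles, fluorescence noise
SD 0.002 and Cq jitter SD 0.05 — values a qPCR practitioner would consider
an unremarkable, well-behaved run.

The recorded Cq is the threshold crossing of the simulated (possibly
noisy) trace, interpolated linearly on the logit of the
baseline-corrected, plateau-normalized signal. The logit of the pure
sigmoid is exactly linear in cycle number, so in the noise-free case this
estimator inverts the curve to floating-point precision — which is what
lets a noise-free dilution series recover the true efficiency to 1e−9
relative through the full document route; a naive linear interpolation
(kept in the tests as an independent oracle) is only good to ~0.05 cycles.
One random stream per document, consumed in fixed order (reactions by
position; per reaction: Cq jitter, amplification noise, melt noise), makes
generation reproducible byte-for-byte through the writer.

What passing tests on this data do **not** show: robustness to baseline
drift, plateau variation between reactions, pipetting error correlated
within replicates, multiplex dye crosstalk, or instruments' proprietary
smoothing — real files exercise none-of-the-above guarantees only at the
container/validation level, not the curve level.

## Problem sizes

The defaults keep everything small and exact: round-trip checks run over
102 generated documents (~12–16 reactions, 40 cycles each) across all
three versions and five plate geometries; the coordinate bijection is
exhaustive over all 700 cells of the shipped formats; the bootstrap uses
10,000 replicates on a 20-point design. The whole acceptance run completes
in seconds.

## Known limitations

* The official XSD schemas are not bundled; rule-based validation covers
  the documented version deltas, and anything else is at most a warning.
* The exact token spelling of version-1.0 plate types is not standardized
  across instruments; unknown tokens require a user-supplied map.
* Reaction data cannot reference a dye directly; the dye is reached via
  the target (an interpretation — multiplex files that tag dyes per data
  entry would carry that tag as an opaque extra).
* Streaming of very large files is not attempted; documents are held fully
  in memory.
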