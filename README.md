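# rdmlkit

Tools for RDML, the Real-time PCR Data Markup Language — the
instrument-independent interchange format for quantitative PCR (qPCR)
experiments. An RDML file is a zip-compressed XML document carrying the
experimenters, samples, targets, dyes, cycling conditions and, per
reaction, the raw fluorescence readings, baseline, quantification
threshold and observed Cq value of a run.

`rdmlkit` is for anyone who has to handle these files outside an
instrument's own software: lab scientists checking or completing exported
runs, reviewers inspecting raw data behind a publication, and developers
who need valid files of every format version to challenge their own
readers and writers. It provides:

* **Reading and writing** the zip+XML container for format versions 1.0,
  1.1 and 1.2 (bare XML is accepted too), with byte-deterministic output
  and verbatim preservation of unknown vendor elements.
* **Validation** with stable issue codes and element paths — duplicate
  identifiers, dangling sample/target/dye references, unregistered dyes
  (mandatory from 1.1), positions off the plate, non-monotone curves,
  elements used outside their version.
* **Migration** between all three versions, in both directions, with a
  machine-readable report of every transformed, synthesized or dropped
  element. Version 1.0 well labels ("B7") are converted to the numeric
  row-major positions used from 1.1 on, and the predefined 1.0 plate types
  to explicit row x column formats.
* **Plate views**: a read-only table reconstruction of the plate, CSV
  export (summary and per-point long form, RFC 4180), and amplification /
  melt curve extraction with deterministic SVG rendering.
* **Standard-curve efficiency**: ordinary least squares of Cq on
  log10(input) over a dilution series. The amplification efficiency is
  E = 10^(−1/slope) (fold-change per cycle; perfect doubling gives E = 2
  and a slope of −3.32 cycles per 10-fold dilution), with its standard
  error from first-order propagation, SE(E) = E·ln10·SE(slope)/slope²,
  or alternatively as the SEM of externally supplied per-curve efficiency
  values. Results can be written back onto the target (the SE element
  exists from version 1.2).
* **Synthetic data**: a deterministic generator of complete, valid
  documents of all three versions with simulated sigmoid amplification
  curves, melt curves, a dilution series with a known true efficiency,
  unknowns and a no-template control — so everything above is testable
  without instrument files.

## Worked example

Generate a 96-well 1.2 document (a 5-step 10-fold dilution series in
duplicate, one unknown, one no-template control), inspect it, and fit the
standard curve:

```sh
$ rdmlkit --quiet generate --seed 4 --unknowns 1 -o demo.rdml
$ rdmlkit info demo.rdml
version: 1.2
experimenters: 1
dyes: 1
samples: 7
targets: 1
experiments: 1
runs: 1
reactions: 12

$ rdmlkit validate demo.rdml
validation successful

$ rdmlkit efficiency demo.rdml --target tgt1
target: tgt1
method: standard-curve
n: 10
slope: -3.59774
intercept: 35.01718
r_squared: 0.999874
efficiency: 1.8965
efficiency_se: 0.0048
```

The ten standard reactions (5 dilutions x 2 replicates) regress Cq on
log10(copies). The slope of −3.60 cycles per 10-fold dilution gives
E = 10^(1/3.598) ≈ 1.90 — each cycle multiplies the product 1.90-fold,
closely recovering the generator's true efficiency of 1.9 — and the
±0.005 standard error comes from the slope's uncertainty. Migration and
export work the same way:

```sh
$ rdmlkit migrate demo.rdml --to 1.0 -o demo_v10.rdml --report report.json
$ rdmlkit export demo.rdml --format svg-amp -o curves.svg
$ rdmlkit export demo.rdml --format csv-summary | head -3
position,well,sample,sampleType,target,dye,cq,baseline,threshold
1,A1,std_1,standard,tgt1,SYBR,16.980382720368606,0.05,0.1
2,A2,std_1,standard,tgt1,SYBR,17.09904445692355,0.05,0.1
```

The same operations are available as a library (`rdmlkit.read_rdml`,
`write_rdml`, `validate`, `migrate`, `plate_table`, `export_csv`,
`extract_curves`, `render_svg`, `fit_standard_curve`,
`generate_document`, ...); see `docs/methods.md` for the underlying models
and design choices.

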