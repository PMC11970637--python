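# hillnet

Logic-based differential-equation (LDE) modeling of signaling and
gene-regulatory networks, for systems biologists who have qualitative
interaction maps ("X activates Y", "Z inhibits Y") but not the kinetic
constants mass-action models demand.

A network is a table of **species** (proteins, genes, stimuli — each a
continuous, dimensionless activity) and **reactions** (directed influence
rules such as `C & !D => E`). From these, hillnet assembles and integrates

```
dyᵢ/dt = ( ymaxᵢ · Fᵢ(y) − yᵢ ) / τᵢ
```

where the drive `Fᵢ` combines normalized Hill responses through continuous
logic gates:

* **activation** `f(x) = B·xⁿ / (Kⁿ + xⁿ)`, with `B = (EC50ⁿ − 1)/(2·EC50ⁿ − 1)`
  and `Kⁿ = B − 1`, the unique scaled Hill curve through `f(0) = 0`,
  `f(EC50) = ½`, `f(1) = 1`;
* **inhibition** `1 − f(x)`;
* **AND** within one reaction: the product of its regulators' Hill terms,
  scaled by the reaction weight `w ∈ [0, 1]`;
* **OR** across reactions sharing a product: `a ⊕ b = a + b − ab`.

Each species carries `(yinit, ymax, τ)` and each reaction `(w, n, EC50)`,
with defaults `τ = 1`, `yinit = 0`, `ymax = 1`, `n = 1.4`, `EC50 = 0.5` that
work well without tuning. Stimuli are weight-switched input reactions
(`=> A`); a gene knockout is `ymax = 0`. Integration uses a stiff implicit
method (BDF) so large, saturated networks remain cheap to simulate.

## Worked example

Two bundled models mirror a classic tutorial pair: `examplenet` (five
generic species with two switchable stimuli, an incoherent AND gate and a
positive feedback loop) and `cardiacdevnet` (a five-transcription-factor
circuit of early heart development in which NKX2-5 represses ISL1).

```python
from hillnet import ProtocolStep, build_examplenet, run_protocol

model = build_examplenet()
traj = run_protocol(model, [
    ProtocolStep(10.0),                       # rest: all stimuli off
    ProtocolStep(10.0, {"r1.weight": 1.0}),   # switch stimulus A on
    ProtocolStep(10.0, {"r1.weight": 0.0}),   # washout
])
print(traj.at_time(20.0).round(4).to_string())
```

prints

```
A    1.0000
B    0.0000
C    0.9998
D    0.0000
E    0.9986
```

— ten time units of stimulation have driven the cascade A → C → E to
saturation (the untouched B branch stays at zero). After the washout
segment, `traj.final().round(4)` shows `A` back at `0.0` while `C` and `E`
hold at `0.9999`: the E → C positive feedback has latched the loop on even
though the stimulus is gone.

The same protocols are scriptable from a shell. The in-silico NKX2-5
knockout (set `ymax` to 0, then stimulate GATA6):

```bash
hillnet scenario cardiacdev-ko --outdir out/
```

```
check	pass	value
max NKX25 <= 0.0	pass	0
ISL1 at end >= 0.99	pass	1
```

The knocked-out gene stays at exactly zero activity, and ISL1 — normally
shut off by NKX2-5 during differentiation — remains fully on, matching the
experimentally observed de-repression. `hillnet simulate model.xlsx --time 2
--set r1.weight=1 --time 8 --out traj.csv` runs ad-hoc protocols (each
`--time` closes a segment; overrides persist until changed),
`hillnet validate` checks model tables, `hillnet steady` reports settled
activities, and `hillnet export --format sif` writes a Cytoscape-loadable
edge list. Models load from an `.xlsx` workbook (sheets `species` and
`reactions`) or a `species.csv`/`reactions.csv` directory; blank cells take
the defaults above, and unknown columns (citations, notes) survive
round-trips untouched.

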