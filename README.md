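# repstress

Quantification of replication stress, cell-cycle-resolved DNA damage, and
drug synergy in cultured cancer cells.

Checkpoint-kinase inhibitors such as ATR inhibitors kill tumor cells by
letting replication stress go unrepaired: forks slow and stall in S phase,
damage persists into G2/M and G0/G1, mis-segregated chromatin ends up in
micronuclei, and the drugs synergize with DNA-damaging chemotherapy. This
package implements, as a tested reusable pipeline, the bespoke
quantification methods used to characterize that cascade in vitro — for
cell biologists running EdU pulse-chase cytometry, multiplexed
immunofluorescence, DNA fiber assays, and combination viability screens,
and for anyone who needs a synthetic, ground-truthed test bed for those
analyses.

## What it computes

**Fraction of DNA replication completion** (`repstress.kinetics`). S-phase
cells are pulse-labeled with EdU and chased through a recovery interval.
With uniform S-phase progress the labeled population starts, on average,
halfway between the 2n and 4n DAPI peaks. Labeled cells that complete S
phase and divide reappear as EdU⁺ 2n cells; half their number is counted,
each at the 4n intensity, giving the adjusted mean W and

    F = (W(t) − W(t0)) / (i_4n − i_2n)

with F = 0 under a full replication block and F = 0.5 when the entire
labeled population completed replication.

**Cell-cycle-resolved damage imaging** (`repstress.imaging`). Nucleus
segmentation from DAPI, per-nucleus phase assignment from EdU + DAPI
(as in a flow cytometry analysis), 53BP1 focus detection with
background-subtracted integrated intensities, p-ATM nuclear intensity,
micronucleus detection with nearest-nucleus association, 1D and 2D
(DAPI-ordered) focus-intensity histograms, and the condition-level
Pearson correlation between G0/G1 damage and micronuclei per cell.

**DNA fiber statistics** (`repstress.fibers`). IdU tract lengths,
per-fiber CIdU/IdU ratios, stalled-fork fractions (CIdU = 0) with Wilson
intervals; Mann-Whitney and Fisher's exact group comparisons.

**Drug synergy by the method of isoboles** (`repstress.synergy`).
Four-parameter-logistic dose-response fits with relative IC50, sensitizer
IC50 fold changes, and the combination index on the 50%-effect isobole

    CI = d1/D1 + d2/D2

where D1, D2 are single-agent IC50s and d1 is the IC50 of drug 1 at fixed
dose d2 of drug 2 (and symmetrically); CI < 1 indicates synergy, 1 Loewe
additivity, > 1 antagonism.

**Synthetic data with ground truth** (`repstress.simulate`): pulse-chase
event tables, rendered four-channel scenes (DAPI / EdU / 53BP1 / p-ATM),
Loewe-additive or synergistic viability plates, fiber tables, and
record-level damage populations.

## Worked example

```python
from repstress.simulate import PulseChaseParams, simulate_pulse_chase
from repstress.kinetics import completion_fraction

control = PulseChaseParams(replication_rate=0.125, recovery_time=7.0, seed=1)
blocked = PulseChaseParams(replication_rate=0.0, recovery_time=7.0, seed=1)
for name, params in [("control", control), ("replication block", blocked)]:
    t0, t = simulate_pulse_chase(params)
    res = completion_fraction(t0, t)
    print(f"{name}: F = {res.fraction_f:.3f} "
          f"({res.n_labeled_t0} labeled cells, {res.n_divided} divided)")
```

prints

```
control: F = 0.491 (6951 labeled cells, 6980 divided)
replication block: F = 0.001 (6951 labeled cells, 0 divided)
```

Healthy replication at 0.125 genome/interval over a 7-interval recovery
lets most labeled cells finish S phase and divide (6980 daughter events),
driving F toward its 0.5 calibration point; blocking replication leaves
the labeled DAPI distribution unchanged and F at zero.

The same assays are available from the shell:

```sh
repstress simulate --kind plate --seed 2 --out plates/
repstress synergy ci --plate plates/plate.csv --n-boot 0
repstress simulate --kind pulsechase --seed 4 --out run/
repstress completion --t0 run/events_t0.csv --t run/events_t.csv
```

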