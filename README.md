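# tldose

Organ and effective dosimetry for infant CT from thermoluminescent
dosimeter (TLD) measurements.

Direct organ-dose measurement in CT is done by embedding calibrated TLD
chips inside an anthropomorphic phantom — here a 1-year-old phantom
scanned head-to-toe under clinical protocols.  `tldose` implements the
full analysis chain for such a campaign, for medical physicists who
measure (or audit) pediatric CT doses:

1. **TLD processing** — per-chip sensitivity factors with ±10 % batch
   rejection, calibration factor (Gy/nC) from a known delivered dose,
   and charge→dose conversion `D = (SF·r − b)·CF` with background
   subtraction and a 20 % repeat-scan consistency check.
2. **Beam model** — simplified filtered-Kramers x-ray spectra (or
   user-supplied spectrum CSVs), aluminium half-value layer, effective
   energy, and the spectrum-weighted water-to-tissue dose conversion
   `f_T = Σ Φ(E)E·[μen/ρ]_T / Σ Φ(E)E·[μen/ρ]_W`.
3. **Organ doses** — pooled mean ± 1 SD per organ with the special
   rules for colon (segment mass weighting), muscle (torso + leg
   average), skin (surface chips) and the skeleton.
4. **Skeletal dosimetry** — red-bone-marrow and shallow-marrow ("bone
   surface") doses `D = Σ_i D_W,i·f_i·(1+S_i)·M_i/M_total` with
   site-specific dose enhancement factors, cellularity and marrow-mass
   weighting.
5. **Effective dose** — ICRP 103 weighted sum `E = Σ w_T·D_T` per sex
   (gonads = testes/ovaries; remainder = mean of the measured remainder
   organs) with propagated standard error, normalised to CTDI_vol.
6. **Software comparison** — percentage variation
   `(D_soft − D_TLD)/D_TLD·100` of Monte Carlo dosimetry-software organ
   doses against the measurements, with hermaphroditic male/female
   averaging and alias-mapped organ vocabularies.

A synthetic-data module generates complete campaigns (chip batches,
readings, placement maps, software tables) from declared ground truth,
and the whole pipeline recovers that truth exactly at zero noise.

See `docs/methods.md` for models, assumptions and limitations.

## Worked example

Simulate a full campaign at the first bundled protocol (80 kVp,
CTDI_vol 8.89 mGy) and process it end to end:

```python
import tldose as t
from tldose.pipeline import process_campaign
from tldose.synthetic_data import ChipBatchSpec

batch = t.generate_chip_batch(115, ChipBatchSpec(), n_outliers=8, seed=42)
chips = t.compute_sensitivity_factors(batch.runs)
print("rejected:", sum(not c.active for c in chips))

truth = t.default_ground_truth("p1", seed=42)       # 5 % readout noise
camp = t.generate_scan_readings(truth, chips)
res = process_campaign(camp.readings, chips, camp.placement, truth.protocol)

print("CF (Gy/nC):", round(res.calibration.cf, 5))
for organ in ("lung", "thyroid", "active_marrow", "bone_surface"):
    r = res.organ_results[organ]
    print(f"{organ}: {r.mean_dose:.2f} +/- {r.sd:.2f} mGy (n={r.n})")
for sex in ("male", "female"):
    e = res.effective[sex]
    print(f"E {sex}: {e.effective_dose:.2f} +/- {e.se:.2f} mSv, "
          f"{e.normalized:.2f} mSv/mGy")
```

Output:

```
rejected: 8
CF (Gy/nC): 0.04998
lung: 20.15 +/- 0.91 mGy (n=24)
thyroid: 21.71 +/- 1.43 mGy (n=4)
active_marrow: 17.78 +/- 0.53 mGy (n=32)
bone_surface: 21.57 +/- 0.66 mGy (n=32)
E male: 18.46 +/- 0.23 mSv, 2.08 mSv/mGy
E female: 18.02 +/- 0.24 mSv, 2.03 mSv/mGy
```

The batch characterisation rejects exactly the 8 constructed
out-of-tolerance chips and recovers the true calibration factor
(0.05 Gy/nC) to 0.04 %.  Organ doses come back at campaign scale
(~20 mGy); the male effective dose exceeds the female because the
testes — lying close to the surface — receive a higher dose than the
ovaries.  `n` counts chip × session measurements (e.g. 12 lung chips ×
2 repeat scans).

The same stages are scriptable from the shell:

```sh
tldose synth --protocol p1 --seed 42 --out campaign/
tldose organs --readings campaign/readings.csv --sf-runs campaign/sf_runs.csv \
              --placement campaign/placement.csv --protocol p1 --out organs.csv
tldose spectrum --kvp 80 --filter Al:5
tldose compare --software software_doses.csv --out variation.csv
```

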