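# segfcs — segmented FCS for confocal line-scan carpets

`segfcs` analyzes two-channel photon-counting line-scan ("carpet")
acquisitions around laser-induced DNA damage, the protocol used to measure
the mobility of DNA-damage sensors such as PARP1 at damage sites in live
cells with a commercial confocal microscope.  It implements **segmented
fluorescence correlation spectroscopy**: the carpet is cut into short
temporal segments, each segment is correlated with segment-local
normalization (which suppresses photobleaching and slow motion), segments
are classified as inside or outside the damage region from a normalized
intensity map, and the zone-averaged correlation curves are fitted with
diffusion/binding models.  A particle-based simulator generates
ground-truth-paired synthetic carpets so every stage is testable without
microscope data.

## The model

For each temporal segment *(i, j)* (column *i*, segment *j*) the correlation
function is estimated as the cross-correlation of the two detection channels
(uncorrelated detector noise cancels):

    G(τ) = ⟨I₁(t) I₂(t+τ)⟩_T / (⟨I₁⟩_T ⟨I₂⟩_T) − 1,

with all averages taken over the segment only.  Zone-averaged curves are
fitted with

* 2D diffusion:  G(τ) = G(∞) + G · (1 + 4Dτ/w₀²)⁻¹
* binding:       G(τ) = G(∞) + G · exp(−τ/τ_B)
* diffusion + binding:  G(τ) = G(∞) + G·[F_D (1 + 4Dτ/w₀²)⁻¹ + F_B exp(−τ/τ_B)],  F_B = 1 − F_D

where *D* is the diffusion coefficient, *w₀* the lateral 1/e² radius of the
detection spot (a calibration input, never fitted), τ_B the bound dwell
time, and F_B the binding fraction.  For noisy curves the binding model is
fitted on lags τ > 20 ms only.  The recruitment trace of the damage region is
fitted with a saturating exponential y = y_B + A_on(1 − e^−(t−t_D)/τ_ACC)
after the damage time t_D and an exponential decay
y = y₀ + A_off e^−(t−t₀)/τ_DEC after the peak.

## Worked example

```bash
python examples/03_zone_acf_and_model_fits.py
```

simulates a 92-s acquisition with a binding strip (τ_B = 0.8 s, D = 3.8
µm²/s), runs the full segmentation/correlation/fitting chain and prints:

```
IN : 59 segments, tau_B = 0.91 s (simulated 0.8 s)
OUT: 275 segments, D = 3.69 um^2/s (simulated 3.8 um^2/s)
two-component binding fraction: F_B(IN) = 0.80, F_B(OUT) = 0.06
```

The damage-region curve shows the slow binding component at close to the
simulated dwell time; outside the strip mobility is purely diffusive, so the
two-component fit puts a large binding fraction inside and almost none
outside.  The other `examples/` scripts cover the simulator, the segment
map, recruitment kinetics and the end-to-end pipeline; the same pipeline is
available from the shell:

```bash
segfcs run --config examples/run.yaml
```

which writes the segment map, zone ACFs, fit tables, quick-look plots and a
JSON report into the configured output directory.

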