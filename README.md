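# frozenframes

Fast preprocessing for facial **micro-expression (ME) spotting**: detect
*frozen frames* — short intervals in which a subject holds a concealed,
motionless pose just before and/or after an involuntary micro-expression —
and hand small groups of frames (GOFs) around them to a downstream spotting
algorithm, discarding most of the video.

## The idea

Motion-sensitive cells in early vision are well modeled by separable
spatio-temporal filters `h(x, y, t) = ρ(x, y)·ψ(t)` with a spatial low-pass
`ρ` and a temporal high-pass `ψ`. Detecting the *absence* of motion is more
robust than detecting the subtle motion of an ME itself, and it becomes a
low-pass problem: choose a temporal low-pass `ϕ` with `ψ = dϕ/dt` and filter
the luminance video `f` two ways,

    G = f ∗ (ρ·ψ)        (LH pair — motion channel)
    F = f ∗ (ρ·ϕ)        (LL pair — smoothed channel)

then track the per-frame spatial standard deviation over the face region Ω,

    σ_U(t) = sqrt( 1/|Ω| · Σ_{x,y} (U(x,y,t) − μ_U(t))² ).

Wherever the video is frozen, `σ_G(t) = 0`, and these zeros coincide with
local extrema of `σ_F(t)`; in face video the concealed pose is the
low-contrast state, so frozen frames surface as **local minima of σ_F** —
which are far easier to pick out than the near-zeros of the noisy σ_G.

The detection pipeline is: partition the clip into stationary scenes → crop
the face ROI → LL filtering → σ_F → local minima → instability removal
(chains of minima closer than `d` frames with values within `τ` of the
signal's energy range are replaced by their midpoint) → keep the `K`
minima of smallest σ_F → place a GOF window around each. A detection
counts as correct when it lies strictly within `N/2` frames of the
annotated ME onset or offset, with `N` the maximal expected ME length
(`N = 64` at 200 Hz, `8` at 25 Hz).

## Worked example

Generate a synthetic clip with one short motion burst (an ME surrogate)
bracketed by two exactly frozen plateaus, then run the detector:

```python
from frozenframes import SpotConfig, SyntheticSpec, generate_sequence, spot

spec = SyntheticSpec(
    T=100, fps=25.0,
    bursts=((48, 51, 20.0, 0.8),),      # frames 48-51: amplitude 20, 0.8 px shift
    plateaus=((44, 47), (52, 55)),      # frozen poses flanking the burst
    noise_std=2.0, seed=7,
)
stack, truth = generate_sequence(spec)
result = spot(stack, SpotConfig(rho_std=3.0, d=2, tau=0.1, K=3))
print("selected minima (ascending sigma):", result.selected_frames)
print("GOF windows:", result.gofs.windows)
print("retained percentage:", result.gofs.retained_percentage)
```

prints

```
selected minima (ascending sigma): [46, 53, 8]
GOF windows: [(3, 12), (41, 50), (48, 57)]
retained percentage: 30
```

The two lowest-σ_F minima (frames 46 and 53) land inside the two frozen
plateaus, within `N/2 = 4` frames of the burst boundaries at 48 and 51; the
third is a noise minimum elsewhere. The three 10-frame GOF windows retain
30% of the clip, so a spotting algorithm would only need to examine
30 of 100 frames.

The same pipeline is scriptable from the shell:

```sh
frozenframes synth -o bench --n-clips 3 --seed 5
frozenframes spot bench/clip_000 --fps 25 --rho-std 3 -d 2 -o out
frozenframes evaluate bench/clip_* --annotations bench/annotations.csv \
    --rho-std 3 -d 2 -o report.json
```

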