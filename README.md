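# filatwist

Analysis toolkit for the **twist landscape of double-protofilament polymers**,
built around the bacterial actin homolog MreB.  MreB forms antiparallel
double protofilaments whose chiral twist couples to membrane binding,
nucleotide state and cell shape; in long molecular-dynamics simulations the
twist angle does not settle at a single value but hops between quasi-stable
states.  `filatwist` turns filament coordinate trajectories (or raw twist
traces) into a quantitative description of that landscape:

1. **Geometry** — each antiparallel subunit pair of the 4×2 lattice gets an
   orthonormal triad (d₁, d₂, d₃): d₃ along the filament, d₂ along the
   inter-protofilament separation (≈ membrane normal), d₁ = d₃ × d₂.  The
   twist angle is the signed rotation about d₃ between the two central
   pairs (the middle 2×2 doublet, avoiding end effects); bending is the
   tilt of d₃ decomposed into in-plane (d₁) and out-of-plane (d₂)
   components.
2. **Buried SASA** — filament-interface stability is tracked as
   bSASA = (A₁ + A₂ − A₁₊₂)/2 from Shrake–Rupley solvent-accessible areas
   (probe radius 1.40 Å, golden-spiral sampling).
3. **Change-point segmentation** — the twist trace is partitioned exactly
   into piecewise-constant Gaussian states by penalized-likelihood dynamic
   programming (nearest-neighbour coupling ε = 0.6, noise stiffness
   k = 0.2, per-changepoint penalty k·log n/ε); per-state means and widths
   are fitted after trimming 5 % of frames at each boundary.
4. **State analysis** — state means pooled across simulations are clustered
   by 1D k-means (the reference ensemble yields four modes near 0°, 5°,
   10° and 12.5°; silhouette scoring makes the cluster count auditable),
   occupancy histograms are built, and each state's torsional stiffness
   follows from equilibrium fluctuations in the small-angle limit:

   K = k_B T l / σ²,  with monomer length l ≈ 5 nm and σ the state's
   angular standard deviation in radians (reported in k_BT·nm and pN·nm²).

A synthetic-data module generates twist traces (piecewise-constant means,
optionally AR(1)-correlated Gaussian noise) and ideal 4×2 lattices realizing
any twist schedule by symmetric counter-rotation of consecutive pairs, so
the whole pipeline is testable end to end without MD output.

Intended users: structural-bioinformatics and filament-mechanics groups who
have trajectory observables (from Anton2/NAMD-style simulations or
elsewhere) and want reproducible state identification and moduli rather
than by-eye annotation.

## Worked example

```python
import filatwist as ft

# Synthetic ATP-bound narrative: ~10.4 deg for almost 1 us, >12 deg for
# 300 ns, then ~4.2 deg (1 ns/frame, sigma = 1 deg).
trace = ft.gen_twist_trace(ft.preset_schedule("atp1", seed=7))
for s in ft.detect_states(trace):
    K = ft.twist_modulus(sigma=s.sigma, temperature=310.0)
    print(f"state [{s.start_frame:4d},{s.end_frame:4d})  mean {s.mean_twist:5.2f} deg  "
          f"sigma {s.sigma:.2f} deg  lifetime {s.lifetime_ns:6.0f} ns  "
          f"K {K.K_kT_nm:6.0f} kBT nm")
```

```
state [   0, 950)  mean 10.32 deg  sigma 0.95 deg  lifetime    950 ns  K  18224 kBT nm
state [ 950,1250)  mean 12.44 deg  sigma 0.98 deg  lifetime    300 ns  K  17017 kBT nm
state [1250,2700)  mean  4.20 deg  sigma 1.02 deg  lifetime   1450 ns  K  15927 kBT nm
```

The detector recovers the three generating states at their exact boundaries
(frames 950 and 1250); each state's mean is within sampling error of the
generating value, and the moduli follow from the ~1° fluctuation width.
Pooling an ensemble reveals the mode structure:

```python
runs = {f"run-{i}": ft.detect_states(t)
        for i, t in enumerate(ft.paper_modes_ensemble(base_seed=1))}
catalog = ft.StateCatalog.from_segments(runs)
print(ft.cluster_state_means(catalog, n_clusters=4, seed=0).centroids)
print(ft.select_n_clusters(catalog, seed=0))
```

```
[ 0.0004  4.9895  9.9789 12.4949]
4
```

— 101 pooled states cluster into the four twist modes, and silhouette
selection confirms k = 4.

The same stages are available from the shell:

```bash
filatwist simulate trace --preset atp1 --seed 7 --out trace.csv
filatwist segment --trace trace.csv --out segments.csv
filatwist cluster --segments "segments*.csv" --k 4 --out catalog.csv
filatwist modulus --catalog catalog.csv --temp 310 --out moduli.csv
filatwist run --config pipeline.yaml        # end-to-end with manifest
```

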