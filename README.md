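# morphosurf

Parametric 3D surface morphology for whole organisms: build mollusk shells,
echinoid tests and basic geometric forms from torus-derived parametric
equation systems, summarize each surface by the six first partial derivatives
of its coordinate functions (the *Jacobian surface summary*), and ordinate
collections of surfaces in a correlation-matrix PCA morphospace.

## The science in one paragraph

Every model is a triple of smooth expressions `x(u, v)`, `y(u, v)`, `z(u, v)`
derived from the ring torus `x = (R + r cos v) cos u`, `y = (R + r cos v) sin u`,
`z = r sin v`. Coiled gastropods wind and taper the torus tube with
exponentials and hyperbolic secants; bivalves, limpets, scaphopods and
echinoids reshape it with sines, cosines and hyperbolic tangents. Evaluating
the six partials `∂(x,y,z)/∂(u,v)` at the reference point `(u, v) = (0, 0)`
yields a 3×2 Jacobian matrix that captures the tangent structure of the whole
surface. Because every generator is homogeneous of degree 1 in its radii, the
summary scales linearly with size; dividing measured radii through by their
smaller member (and optionally reducing to a lowest-integer ratio) makes it a
size-free shape descriptor. Collections of summaries are standardized and
eigendecomposed (correlation-matrix PCA) to give an empirical morphospace in
which ontogenetic series trace trajectories — linear for isometric growth —
and rare Jacobian-degenerate model pairs are discriminated by second partial
derivatives (Hessian post-processing).

## Worked example

```python
>>> from morphosurf import (canonical_model, jacobian, assemble_table,
...                         ordinate, fixture_collection,
...                         RadiiMeasurement, reduce_measurement)

# a volute shell from the registered coefficient recipe
>>> J = jacobian(canonical_model("volute"))
>>> [round(x, 6) for x in J.flat]          # (dx_du, dx_dv, dy_du, dy_dv, dz_du, dz_dv)
[-1.671127, 0.0, 10.5, 0.0, -0.322289, 2.0]

# ordinate the frozen 17-model mollusk/echinoid collection
>>> space = ordinate(assemble_table(fixture_collection("mollusk_echinoid").models))
>>> [round(x, 4) for x in space.eigenvalues]
[3.1368, 1.1062, 0.8947, 0.5579, 0.2449, 0.0595]
>>> round(space.cumulative_percent[1], 3)  # first two PCs
70.716

# reduce a measured shell (radii in cm) to its proportions
>>> reduce_measurement(RadiiMeasurement("Architectonica nobilis", 1.45, 0.4))
Proportion(actual=(3.625, 1.0), integer=(4, 1))
```

The eigenvalues sum to 6 (the retained variable count), the structural
guarantee of correlation-matrix PCA. The turritellid growth series (5–12
whorls) ordinated in the same space yields a perfectly linear trajectory
(collinearity 1.000000) with equally spaced, monotone stage projections
−1.106, −0.790, … , 1.106 — isometric accretionary growth.

## Command line

```sh
morphosurf fixtures mollusk_echinoid -o specs/      # model-spec JSON files
morphosurf build specs/volute.json -o volute.obj    # OBJ/PLY point cloud
morphosurf jacobian --collection mollusk_echinoid -o jac.csv --hessian
morphosurf ordinate jac.csv -o morpho               # .eigen/.scores/.correlations
morphosurf measure radii.csv -o report.csv          # proportion reduction
```

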