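"""Model-spec documents, point-cloud and table export, fixture collections.

Model specs are JSON documents (kind, coefficients, domain, grid resolution,
evaluation point, label) that round-trip losslessly; grids export to OBJ or
ascii PLY point clouds readable by standard mesh tools; Jacobian tables
serialize to CSV at 12 significant digits.  Fixture collections freeze the
model populations used for the worked ordinations so downstream numbers are
reproducible.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffgeo import JACOBIAN_ELEMENT_ORDER
from .morphospace import JacobianTable
from .surfaces import (
    MorphosurfError,
    ParameterDomain,
    RegistryError,
    SurfaceGrid,
    SurfaceModel,
    canonical_model,
    make_model,
)

__all__ = [
    "ExportError",
    "ParseError",
    "ModelSpec",
    "FixtureCollection",
    "FIXTURE_NAMES",
    "model_to_spec",
    "spec_to_model",
    "write_model_spec",
    "read_model_spec",
    "write_point_cloud",
    "write_jacobian_table",
    "read_jacobian_table",
    "fixture_collection",
]


class ExportError(MorphosurfError):
    """Attempt to export an empty grid or table."""


class ParseError(MorphosurfError):
    """A malformed model-spec document."""


_SPEC_KEYS = {"kind", "coefficients", "domain", "nu", "nv", "eval_point", "label"}


@dataclass(frozen=True)
class ModelSpec:
    """JSON-compatible description of one surface model.

    ``nu``/``nv`` and ``eval_point`` are defaults for grid export and
    Jacobian evaluation; they do not affect the model itself.
    """

    kind: str
    coefficients: dict[str, float]
    domain: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 6.283185307179586),) * 2
    nu: int = 64
    nv: int = 32
    eval_point: tuple[float, float] = (0.0, 0.0)
    label: str | None = None

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "coefficients": dict(self.coefficients),
            "domain": [list(self.domain[0]), list(self.domain[1])],
            "nu": self.nu,
            "nv": self.nv,
            "eval_point": list(self.eval_point),
            "label": self.label,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, document: str) -> "ModelSpec":
        try:
            payload = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ParseError(
                f"malformed model spec at line {exc.lineno}, column {exc.colno}: {exc.msg}"
            ) from exc
        if not isinstance(payload, dict):
            raise ParseError("model spec must be a JSON object")
        unknown = set(payload) - _SPEC_KEYS
        if unknown:
            raise ParseError(f"unknown model-spec key(s): {sorted(unknown)}")
        if "kind" not in payload or "coefficients" not in payload:
            raise ParseError("model spec requires 'kind' and 'coefficients'")
        dom = payload.get("domain")
        domain = (
            (tuple(map(float, dom[0])), tuple(map(float, dom[1])))
            if dom is not None
            else ((0.0, 2 * np.pi), (0.0, 2 * np.pi))
        )
        ep = payload.get("eval_point", (0.0, 0.0))
        return cls(
            kind=str(payload["kind"]),
            coefficients={str(k): float(v) for k, v in payload["coefficients"].items()},
            domain=domain,
            nu=int(payload.get("nu", 64)),
            nv=int(payload.get("nv", 32)),
            eval_point=(float(ep[0]), float(ep[1])),
            label=payload.get("label"),
        )


def model_to_spec(model: SurfaceModel, nu: int = 64, nv: int = 32) -> ModelSpec:
    """Describe a registry-built model as a spec document."""
    if model.kind is None:
        raise ExportError("models built from raw expressions have no spec representation")
    return ModelSpec(
        kind=model.kind.value,
        coefficients=model.coefficients.as_dict(),
        domain=(model.domain.u_range, model.domain.v_range),
        nu=nu,
        nv=nv,
        label=model.label,
    )


def spec_to_model(spec: ModelSpec) -> SurfaceModel:
    domain = ParameterDomain(u_range=spec.domain[0], v_range=spec.domain[1])
    return make_model(spec.kind, spec.coefficients, domain=domain, label=spec.label)


def write_model_spec(model: SurfaceModel) -> str:
    return model_to_spec(model).to_json()


def read_model_spec(document: str) -> SurfaceModel:
    """Parse a JSON model spec and build the model.

    Unknown kinds raise :class:`~morphosurf.surfaces.RegistryError`;
    malformed documents raise :class:`ParseError` with line context.
    """
    return spec_to_model(ModelSpec.from_json(document))


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def write_point_cloud(
    grid: SurfaceGrid, format: str = "obj", faces: bool = False
) -> str:
    """Serialize a surface grid as an OBJ or ascii PLY document.

    OBJ emits one ``v x y z`` line per lattice point (v varying fastest),
    optionally followed by quad faces over the lattice; PLY emits a standard
    ascii header with ``element vertex nu*nv``.  Coordinates use fixed
    9-decimal formatting.
    """
    if grid.n_points == 0:
        raise ExportError("cannot export an empty grid")
    pts = grid.flat_points()
    if format == "obj":
        out = _io.StringIO()
        for x, y, z in pts:
            out.write(f"v {x:.9f} {y:.9f} {z:.9f}\n")
        if faces:
            for i in range(grid.nu - 1):
                for j in range(grid.nv - 1):
                    a = i * grid.nv + j + 1  # OBJ indices are 1-based
                    b = a + 1
                    c = a + grid.nv + 1
                    d = a + grid.nv
                    out.write(f"f {a} {b} {c} {d}\n")
        return out.getvalue()
    if format in ("ply", "ply_ascii"):
        header = (
            "ply\n"
            "format ascii 1.0\n"
            f"element vertex {grid.n_points}\n"
            "property float x\n"
            "property float y\n"
            "property float z\n"
            "end_header\n"
        )
        body = "".join(f"{x:.9f} {y:.9f} {z:.9f}\n" for x, y, z in pts)
        return header + body
    raise ExportError(f"unknown point-cloud format {format!r} (use 'obj' or 'ply_ascii')")


# ---------------------------------------------------------------------------
# Jacobian tables
# ---------------------------------------------------------------------------

def write_jacobian_table(table: JacobianTable) -> str:
    """CSV document: header ``label,dx_du,...``, one row per model, %.12g."""
    lines = ["label," + ",".join(JACOBIAN_ELEMENT_ORDER)]
    for label, row in zip(table.labels, table.matrix):
        lines.append(label + "," + ",".join(f"{x if x != 0 else 0.0:.12g}" for x in row))
    return "\n".join(lines) + "\n"


def read_jacobian_table(document: str) -> JacobianTable:
    df = pd.read_csv(_io.StringIO(document))
    expected = ["label", *JACOBIAN_ELEMENT_ORDER]
    if list(df.columns) != expected:
        raise ParseError(f"Jacobian table must have columns {expected}, got {list(df.columns)}")
    labels = tuple(str(x) for x in df["label"])
    matrix = df[list(JACOBIAN_ELEMENT_ORDER)].to_numpy(dtype=float)
    return JacobianTable(labels=labels, matrix=matrix)


# ---------------------------------------------------------------------------
# fixture collections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureCollection:
    """A named, ordered, uniquely labeled collection of surface models."""

    name: str
    models: tuple[SurfaceModel, ...]

    def __post_init__(self) -> None:
        labels = [m.label for m in self.models]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate labels in collection {self.name!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(m.label for m in self.models)

    def as_mapping(self) -> dict[str, SurfaceModel]:
        return {m.label: m for m in self.models}


def _mollusk_echinoid() -> list[str]:
    # one instance of each generating system, including the printed recipes
    return [
        "cone_shell", "volute", "olive", "melampus", "sundial", "bubble",
        "moon_snail",
        "turritellid(8)", "vermicularia(9)", "spiral(5)",
        "limpet", "clam", "oyster", "scallop",
        "ammonite(3, 8)", "scaphopod", "echinoid",
    ]


def _basic_forms() -> list[str]:
    # the seven basic geometric forms plus bivalve/gastropod variants
    return [
        "torus", "cylinder", "cone", "dome", "sphere",
        "ellipsoid(1.5)", "ellipsoid(2.5)",
        "clam", "oyster", "scallop",
        "volute", "melampus", "turritellid(6)", "ammonite(3, 8)",
    ]


def _turritellid_series() -> list[str]:
    return [f"turritellid({n})" for n in range(5, 13)]


def _ammonite_grid() -> list[str]:
    return [f"ammonite({l}, {q})" for l in (2.0, 3.0, 4.0) for q in (6.0, 8.0, 10.0)]


_FIXTURES = {
    "mollusk_echinoid": _mollusk_echinoid,
    "basic_forms": _basic_forms,
    "turritellid_series": _turritellid_series,
    "ammonite_grid": _ammonite_grid,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture_collection(name: str) -> FixtureCollection:
    """Build one of the frozen model collections by name.

    ``mollusk_echinoid`` holds one instance of every generating system
    (printed recipes included); ``basic_forms`` the seven basic geometric
    forms plus bivalve/gastropod variants; ``turritellid_series`` the eight
    isometric growth stages with 5 to 12 whorls; ``ammonite_grid`` a 3x3
    sweep of coiling (l) against pleating (q).
    """
    try:
        recipe = _FIXTURES[name]
    except KeyError as exc:
        raise RegistryError(
            f"unknown fixture collection {name!r}; known: {', '.join(FIXTURE_NAMES)}"
        ) from exc
    return FixtureCollection(name=name, models=tuple(canonical_model(n) for n in recipe()))
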