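"""Plate layouts, well records and tabular screen I/O.

A screen is a collection of 96-well plates imaged in replicate.  Each well
carries a vector of named numeric readouts (84 by default) summarising the
imaging output, plus its position, its role (sample / negative control /
positive control / empty) and the identity of the siRNA it received.

Well coordinates follow plate convention: a row letter A-H and a 1-based
column number, e.g. ``"A1"``.  Internally rows map A->1 ... H->8 so that
positional artifact models can regress on row and column numbers.
"""

from __future__ import annotations

import dataclasses
import string
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, PlateLookupError, SchemaError

ROLE_SAMPLE = "sample"
ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLE_EMPTY = "empty"
ROLES = (ROLE_SAMPLE, ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_EMPTY)

#: The three readouts every workflow can reference by stable key.
NAMED_READOUTS = (
    "pct_cells_gt3_puncta",
    "puncta_area_per_cell",
    "puncta_intensity_per_cell",
)

META_COLUMNS = ("plate_id", "replicate", "well", "role", "gene_id", "sirna_id")

_ROW_LETTERS = string.ascii_uppercase[:8]


def well_to_rc(well: str) -> tuple[int, int]:
    """Convert ``"A1"`` -> ``(1, 1)``; rows A-H map to 1-8, columns stay 1-based."""
    well = well.strip().upper()
    if len(well) < 2 or well[0] not in _ROW_LETTERS:
        raise ValueError(f"malformed well coordinate: {well!r}")
    row = _ROW_LETTERS.index(well[0]) + 1
    try:
        col = int(well[1:])
    except ValueError as exc:
        raise ValueError(f"malformed well coordinate: {well!r}") from exc
    if not 1 <= col <= 12:
        raise ValueError(f"column out of range in well {well!r}")
    return row, col


def rc_to_well(row: int, col: int) -> str:
    return f"{_ROW_LETTERS[row - 1]}{col}"


def all_wells(n_rows: int = 8, n_cols: int = 12) -> list[str]:
    """All well names of a plate in row-major order (A1, A2, ... H12)."""
    return [rc_to_well(r, c) for r in range(1, n_rows + 1) for c in range(1, n_cols + 1)]


@dataclasses.dataclass(frozen=True)
class PlateLayout:
    """Role assignment of every well on a plate."""

    layout_name: str
    role_map: dict[str, str]
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self) -> None:
        expected = set(all_wells(self.n_rows, self.n_cols))
        got = set(self.role_map)
        if got != expected:
            missing = sorted(expected - got)[:5]
            extra = sorted(got - expected)[:5]
            raise ConsistencyError(
                f"layout {self.layout_name!r} must cover every well exactly once "
                f"(missing {missing}, unexpected {extra})"
            )
        bad = {r for r in self.role_map.values() if r not in ROLES}
        if bad:
            raise ConsistencyError(f"unknown roles in layout: {sorted(bad)}")

    def role(self, well: str) -> str:
        return self.role_map[well.strip().upper()]

    def wells_of_role(self, role: str) -> list[str]:
        """Wells with the given role, in row-major order."""
        return [w for w in all_wells(self.n_rows, self.n_cols) if self.role_map[w] == role]


def _layout_from_controls(name: str, negative: Iterable[str], positive: Iterable[str]) -> PlateLayout:
    role_map = {w: ROLE_SAMPLE for w in all_wells()}
    for w in negative:
        role_map[w] = ROLE_NEGATIVE
    for w in positive:
        role_map[w] = ROLE_POSITIVE
    return PlateLayout(layout_name=name, role_map=role_map)


# Primary screen: non-targeting controls down the outer corners of columns 1/12,
# PINK1-targeting positive controls mirrored.  Secondary screen scatters the
# controls across the plate to decorrelate them from row/column gradients.
BUILTIN_LAYOUTS: dict[str, PlateLayout] = {
    "primary": _layout_from_controls(
        "primary",
        negative=("A1", "B1", "C1", "D1", "E12", "F12", "G12", "H12"),
        positive=("A12", "B12", "C12", "D12", "E1", "F1", "G1", "H1"),
    ),
    "secondary": _layout_from_controls(
        "secondary",
        negative=("A2", "A12", "C5", "C8", "D10", "E3", "F5", "F8", "H2", "H12"),
        positive=("A1", "A11", "C4", "C9", "F4", "F9", "H1", "H11"),
    ),
}


def get_layout(name: str | PlateLayout) -> PlateLayout:
    if isinstance(name, PlateLayout):
        return name
    try:
        return BUILTIN_LAYOUTS[name]
    except KeyError:
        raise PlateLookupError(f"unknown layout {name!r}; built-ins: {sorted(BUILTIN_LAYOUTS)}")


@dataclasses.dataclass
class WellRecord:
    """One well of one plate replicate."""

    plate_id: str
    replicate: int
    well: str
    role: str
    gene_id: str | None
    sirna_id: str | None
    readouts: dict[str, float]

    @property
    def row(self) -> int:
        return well_to_rc(self.well)[0]

    @property
    def col(self) -> int:
        return well_to_rc(self.well)[1]


def default_parameter_names(n_parameters: int = 84) -> list[str]:
    """The default registry: the three named readouts then numbered fillers."""
    if n_parameters < len(NAMED_READOUTS):
        raise ValueError("need at least the three named readouts")
    names = list(NAMED_READOUTS)
    names += [f"param_{i:02d}" for i in range(len(names) + 1, n_parameters + 1)]
    return names


class ScreenDataset:
    """A full screen: plates x replicates of wells plus the parameter registry.

    The well table is a :class:`pandas.DataFrame` with the metadata columns
    ``plate_id, replicate, well, role, gene_id, sirna_id`` followed by one
    float column per registered parameter.  Missing readouts are NaN and
    propagate through downstream medians/MADs by pairwise deletion.
    """

    def __init__(
        self,
        layout: PlateLayout | str,
        parameter_names: Sequence[str],
        wells: pd.DataFrame,
        validate: bool = True,
    ) -> None:
        self.layout = get_layout(layout)
        self.parameter_names = list(parameter_names)
        wells = wells.reset_index(drop=True).copy()
        # normalise dtypes
        if len(wells):
            wells["replicate"] = wells["replicate"].astype(int)
            wells["well"] = wells["well"].astype(str).str.upper()
            for col in ("gene_id", "sirna_id"):
                wells[col] = wells[col].astype(object).where(pd.notna(wells[col]), None)
            for p in self.parameter_names:
                wells[p] = pd.to_numeric(wells[p], errors="raise").astype(float)
        self.wells = wells
        if validate:
            self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.wells.columns]
        missing += [p for p in self.parameter_names if p not in self.wells.columns]
        if missing:
            raise SchemaError(f"well table missing columns: {missing}")
        for named in NAMED_READOUTS:
            if named not in self.parameter_names:
                raise SchemaError(f"parameter registry must include {named!r}")
        if not len(self.wells):
            return
        expected = self.wells["well"].map(self.layout.role_map)
        bad = self.wells["role"] != expected
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            r = self.wells.iloc[i]
            raise ConsistencyError(
                f"role {r['role']!r} at {r['plate_id']}/{r['replicate']}/{r['well']} "
                f"contradicts layout {self.layout.layout_name!r} ({expected.iloc[i]!r})"
            )
        dup = self.wells.duplicated(subset=["plate_id", "replicate", "well"])
        if dup.any():
            r = self.wells[dup].iloc[0]
            raise ConsistencyError(
                f"well {r['well']} appears twice in plate {r['plate_id']} replicate {r['replicate']}"
            )
        is_control = self.wells["role"].isin([ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_EMPTY])
        if self.wells.loc[is_control, "gene_id"].notna().any():
            raise ConsistencyError("control/empty wells must have null gene_id")
        if (self.wells.loc[self.wells["role"] == ROLE_SAMPLE, "gene_id"]).isna().any():
            raise ConsistencyError("sample wells must carry a gene_id")

    # -- convenience ---------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def plate_replicates(self) -> list[tuple[str, int]]:
        if not len(self.wells):
            return []
        pairs = self.wells[["plate_id", "replicate"]].drop_duplicates()
        return [(str(p), int(r)) for p, r in pairs.itertuples(index=False)]

    def subset(self, mask: pd.Series) -> "ScreenDataset":
        return ScreenDataset(self.layout, self.parameter_names, self.wells[mask], validate=False)

    def control_wells(self, plate_id: str, replicate: int, role: str) -> list[WellRecord]:
        """Wells of the given role on one plate replicate, in row-major order."""
        sel = (self.wells["plate_id"] == plate_id) & (self.wells["replicate"] == int(replicate))
        if not sel.any():
            raise PlateLookupError(f"no plate {plate_id!r} replicate {replicate}")
        sub = self.wells[sel & (self.wells["role"] == role)]
        order = {w: i for i, w in enumerate(all_wells(self.layout.n_rows, self.layout.n_cols))}
        sub = sub.iloc[np.argsort([order[w] for w in sub["well"]], kind="stable")]
        return [self._record(row) for _, row in sub.iterrows()]

    def _record(self, row: pd.Series) -> WellRecord:
        return WellRecord(
            plate_id=str(row["plate_id"]),
            replicate=int(row["replicate"]),
            well=str(row["well"]),
            role=str(row["role"]),
            gene_id=row["gene_id"],
            sirna_id=row["sirna_id"],
            readouts={p: float(row[p]) for p in self.parameter_names},
        )

    def control_values(self, plate_id: str, replicate: int, role: str, parameter: str) -> np.ndarray:
        if parameter not in self.parameter_names:
            raise PlateLookupError(f"unknown parameter {parameter!r}")
        sel = (
            (self.wells["plate_id"] == plate_id)
            & (self.wells["replicate"] == int(replicate))
            & (self.wells["role"] == role)
        )
        return self.wells.loc[sel, parameter].to_numpy(dtype=float)

    def equals(self, other: "ScreenDataset") -> bool:
        if self.layout.layout_name != other.layout.layout_name:
            return False
        if self.parameter_names != other.parameter_names:
            return False
        a = self.wells.reset_index(drop=True)
        b = other.wells.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True

    def copy(self) -> "ScreenDataset":
        return ScreenDataset(self.layout, self.parameter_names, self.wells.copy(), validate=False)


def read_screen(path, layout_name: str | PlateLayout = "primary") -> ScreenDataset:
    """Read a per-well summary CSV into a validated :class:`ScreenDataset`.

    The file must carry the metadata columns ``plate_id, replicate, well,
    gene_id, sirna_id`` (``role`` is optional and, when present, must agree
    with the named layout) followed by one numeric column per parameter.
    """
    layout = get_layout(layout_name)
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "gene_id": str, "sirna_id": str})
    required = [c for c in META_COLUMNS if c != "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    params = [c for c in df.columns if c not in META_COLUMNS]
    if "role" not in df.columns:
        df["role"] = df["well"].astype(str).str.upper().map(layout.role_map)
    for p in params:
        try:
            df[p] = pd.to_numeric(df[p], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[p], errors="coerce").isna() & df[p].notna()
            row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else -1
            raise SchemaError(f"{path}: non-numeric readout in column {p!r}, data row {row}") from exc
    df = df[list(META_COLUMNS) + params]
    return ScreenDataset(layout, params, df)


def read_screen_config(path) -> dict:
    """Read a small YAML/JSON screen config.

    Recognised keys: ``layout`` (built-in name), ``replicates_per_plate``,
    ``parameter_names`` (optional; defaults to the 84-name registry with
    ``n_parameters`` entries).
    """
    import json

    import yaml

    text = open(path).read()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    layout = get_layout(cfg.get("layout", "primary"))
    params = cfg.get("parameter_names") or default_parameter_names(int(cfg.get("n_parameters", 84)))
    for named in NAMED_READOUTS:
        if named not in params:
            raise SchemaError(f"config parameter registry must include {named!r}")
    return {
        "layout": layout,
        "replicates_per_plate": int(cfg.get("replicates_per_plate", 3)),
        "parameter_names": list(params),
    }


def write_screen(dataset: ScreenDataset, path) -> str:
    """Write a dataset as CSV readable by :func:`read_screen` (full precision)."""
    df = dataset.wells[list(META_COLUMNS) + dataset.parameter_names]
    df.to_csv(path, index=False)
    return str(path)
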