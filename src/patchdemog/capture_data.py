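"""Domain types and I/O for robust-design capture histories and density records.

The robust design organises trapping into T primary sessions (assumed
demographically closed) of K secondary occasions each, separated by longer
open intervals.  An individual's data is a T x K binary encounter matrix plus
an age class (young / adult, by tooth eruption) at every capture.

Two file routes are supported:

* long-format CSV (columns ``individual_id, patch_id, session, occasion,
  age`` — one row per capture), which round-trips the full data model; and
* the MARK ``.inp`` encounter-history format (session-major 0/1 string, one
  frequency column per patch group, ``/* id */`` comments, semicolon
  terminated).  ``.inp`` carries no age information, so reading assigns
  ``adult`` throughout; round-tripping is exact on encounter matrices, patch
  assignment and ids.

Sessions and occasions are 1-based everywhere in I/O and reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

YOUNG = "young"
ADULT = "adult"
VALID_LANDSCAPES = (50, 30, 10)


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


# ---------------------------------------------------------------------------
# design and record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Layout of a robust-design trapping study.

    Parameters
    ----------
    n_primary:
        Number of primary sessions T (>= 2).
    n_secondary:
        Secondary occasions per primary session (constant K >= 2; recaptures
        within a session are required to identify the recapture rate c).
    patches:
        Tuple of ``(patch_id, landscape_class)`` with landscape class in
        percent forest cover (50, 30 or 10).
    interval_days:
        Days between primary sessions (metadata only).
    trap_stations:
        Optional per-grid trap counts, e.g. ``{"sherman": 121, "pitfall": 55}``.
    """

    n_primary: int
    n_secondary: int
    patches: tuple[tuple[str, int], ...]
    interval_days: int = 20
    trap_stations: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_primary < 2:
            raise ValueError("need at least 2 primary sessions")
        if self.n_secondary < 2:
            raise ValueError("need at least 2 secondary occasions per session")
        ids = [p for p, _ in self.patches]
        if len(set(ids)) != len(ids):
            raise ValueError("patch ids must be unique")
        for _, ls in self.patches:
            if ls not in VALID_LANDSCAPES:
                raise ValueError(f"landscape class must be one of {VALID_LANDSCAPES}")

    @property
    def patch_ids(self) -> list[str]:
        return [p for p, _ in self.patches]

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def landscape_of(self, patch_id: str) -> int:
        for p, ls in self.patches:
            if p == patch_id:
                return ls
        raise KeyError(f"unknown patch id: {patch_id!r}")

    @property
    def landscapes(self) -> list[int]:
        """Distinct landscape classes, in order of first appearance."""
        seen: list[int] = []
        for _, ls in self.patches:
            if ls not in seen:
                seen.append(ls)
        return seen

    def total_trap_nights(self) -> int:
        """Total trap nights: traps per grid x grids x trapping nights.

        Requires ``trap_stations``; a grid contributes the sum of its trap
        counts on each of the ``n_primary * n_secondary`` trapping nights.
        """
        if not self.trap_stations:
            raise ValueError("trap_stations metadata required")
        traps = sum(self.trap_stations.values())
        return traps * self.n_patches * self.n_primary * self.n_secondary


@dataclass
class EncounterRecord:
    """One individual's T x K binary encounter matrix with per-capture ages.

    ``age`` is an object array of the same shape holding ``"young"`` /
    ``"adult"`` exactly where ``encounters == 1`` and ``None`` elsewhere.
    Ages may never transition adult -> young in chronological
    (session-major, then occasion) order.
    """

    individual_id: str
    patch_id: str
    encounters: np.ndarray
    age: np.ndarray
    sex: str | None = None

    def __post_init__(self) -> None:
        self.encounters = np.asarray(self.encounters, dtype=np.int8)
        if self.encounters.ndim != 2:
            raise ValueError("encounters must be a T x K matrix")
        if not np.isin(self.encounters, (0, 1)).all():
            raise ValueError("encounters must be binary")
        if not self.encounters.any():
            raise ValueError(
                f"individual {self.individual_id!r} has an all-zero encounter "
                "matrix; never-captured individuals cannot appear in the data"
            )
        self.age = np.asarray(self.age, dtype=object)
        if self.age.shape != self.encounters.shape:
            raise ValueError("age array must match encounter matrix shape")
        cap = self.encounters == 1
        vals = self.age[cap]
        if not all(v in (YOUNG, ADULT) for v in vals):
            raise ValueError("age must be 'young' or 'adult' at every capture")
        if any(v is not None for v in self.age[~cap]):
            raise ValueError("age must be None where there is no capture")
        seq = [v for v in self.age.ravel() if v is not None]
        for a, b in zip(seq, seq[1:]):
            if a == ADULT and b == YOUNG:
                raise ValueError(
                    f"individual {self.individual_id!r} transitions adult -> young"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.encounters.shape


@dataclass(frozen=True)
class CollapsedHistory:
    """Primary-session summary of an encounter matrix (1-based first/last)."""

    detected: tuple[int, ...]
    first: int
    last: int

    def __post_init__(self) -> None:
        if not any(self.detected):
            raise ValueError("collapsed history must contain at least one detection")
        if self.first > self.last:
            raise ValueError("first session must not exceed last")


@dataclass(frozen=True)
class DensityRecord:
    """One surveyed patch: landscape context, area and density index.

    ``count`` is the number of distinct individuals captured under the
    standardized line protocol, used as an index of population density.
    """

    patch_id: str
    landscape_class: int
    area_ha: float
    count: int

    def __post_init__(self) -> None:
        if self.landscape_class not in VALID_LANDSCAPES:
            raise ValueError(f"landscape class must be one of {VALID_LANDSCAPES}")
        if not self.area_ha > 0:
            raise ValueError("patch area must be positive")
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError("count must be a non-negative integer")


@dataclass
class RobustDesignDataset:
    """A study design plus the encounter records observed under it."""

    design: StudyDesign
    records: list[EncounterRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = (self.design.n_primary, self.design.n_secondary)
        known = set(self.design.patch_ids)
        for rec in self.records:
            if rec.shape != shape:
                raise ValueError(
                    f"record {rec.individual_id!r} has shape {rec.shape}, "
                    f"design requires {shape}"
                )
            if rec.patch_id not in known:
                raise KeyError(f"unknown patch id: {rec.patch_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def by_patch(self) -> dict[str, list[EncounterRecord]]:
        out: dict[str, list[EncounterRecord]] = {p: [] for p in self.design.patch_ids}
        for rec in self.records:
            out[rec.patch_id].append(rec)
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def collapse(rec: EncounterRecord) -> CollapsedHistory:
    """Collapse secondary occasions: detected in session t iff any capture there."""
    det = tuple(int(x) for x in (rec.encounters.sum(axis=1) > 0))
    idx = [i + 1 for i, d in enumerate(det) if d]
    return CollapsedHistory(detected=det, first=idx[0], last=idx[-1])


def reduce_to_adults(
    data: RobustDesignDataset, drop_ever_young: bool = False
) -> RobustDesignDataset:
    """Remove captures made while young; drop individuals with no adult captures.

    An animal first caught young and later adult was born on the grid, so its
    adult reappearance must not look like an immigrant arrival: by default its
    young encounters are erased and the adult ones kept.  With
    ``drop_ever_young=True`` any individual ever recorded young is dropped
    entirely (the stricter reading).
    """
    kept: list[EncounterRecord] = []
    for rec in data.records:
        ages = rec.age
        if drop_ever_young and any(a == YOUNG for a in ages[rec.encounters == 1]):
            continue
        enc = rec.encounters.copy()
        new_age = ages.copy()
        young_mask = np.frompyfunc(lambda a: a == YOUNG, 1, 1)(ages).astype(bool)
        enc[young_mask] = 0
        new_age[young_mask] = None
        if not enc.any():
            continue
        kept.append(
            EncounterRecord(rec.individual_id, rec.patch_id, enc, new_age, rec.sex)
        )
    return RobustDesignDataset(design=data.design, records=kept)


def mt1_per_session(data: RobustDesignDataset) -> pd.DataFrame:
    """Distinct individuals captured (M_{t+1}) per patch x primary session.

    Rows are patch ids (design order), columns 1..T.
    """
    T = data.design.n_primary
    table = pd.DataFrame(
        0, index=data.design.patch_ids, columns=range(1, T + 1), dtype=int
    )
    for rec in data.records:
        seen = rec.encounters.sum(axis=1) > 0
        for t in np.nonzero(seen)[0]:
            table.loc[rec.patch_id, t + 1] += 1
    table.index.name = "patch_id"
    table.columns.name = "session"
    return table


# ---------------------------------------------------------------------------
# MARK .inp I/O
# ---------------------------------------------------------------------------

_INP_LINE = re.compile(
    r"^\s*(?:/\*(?P<comment>.*?)\*/)?\s*(?P<hist>[01]+)\s+(?P<freqs>[-\d\s.]+);\s*$"
)


def write_inp(path: str | Path, data: RobustDesignDataset) -> None:
    """Write a MARK ``.inp`` encounter-history file.

    One line per individual: ``/* id */ history  f_1 ... f_G;`` where the
    history concatenates sessions in order (session-major) and the frequency
    columns are one per patch (1 in the individual's patch, 0 elsewhere).
    """
    patch_ids = data.design.patch_ids
    lines = []
    for rec in data.records:
        hist = "".join(str(int(x)) for x in rec.encounters.ravel())
        freqs = " ".join("1" if p == rec.patch_id else "0" for p in patch_ids)
        lines.append(f"/* {rec.individual_id} */ {hist} {freqs};")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_inp(path: str | Path, design: StudyDesign) -> RobustDesignDataset:
    """Read a MARK ``.inp`` file against a known design.

    The format does not encode age classes, so every capture is recorded as
    adult.  Errors (ragged history, non-binary characters, missing semicolon,
    bad frequency columns) name the offending line number.
    """
    T, K = design.n_primary, design.n_secondary
    patch_ids = design.patch_ids
    records: list[EncounterRecord] = []
    anon = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        if not raw.rstrip().endswith(";"):
            raise ParseError(f"line {lineno}: missing terminating ';'")
        m = _INP_LINE.match(raw)
        if m is None:
            raise ParseError(f"line {lineno}: malformed .inp line")
        hist = m.group("hist")
        if len(hist) != T * K:
            raise ParseError(
                f"line {lineno}: history length {len(hist)}, expected {T * K}"
            )
        freqs = [float(x) for x in m.group("freqs").split()]
        if len(freqs) != len(patch_ids):
            raise ParseError(
                f"line {lineno}: {len(freqs)} group columns, "
                f"expected {len(patch_ids)}"
            )
        hot = [i for i, f in enumerate(freqs) if f != 0]
        if len(hot) != 1:
            raise ParseError(
                f"line {lineno}: exactly one nonzero group column required"
            )
        comment = m.group("comment")
        if comment is not None and comment.strip():
            ind_id = comment.strip()
        else:
            anon += 1
            ind_id = f"ind{anon:04d}"
        enc = np.array([int(ch) for ch in hist], dtype=np.int8).reshape(T, K)
        age = np.full((T, K), None, dtype=object)
        age[enc == 1] = ADULT
        records.append(
            EncounterRecord(ind_id, patch_ids[hot[0]], enc, age)
        )
    return RobustDesignDataset(design=design, records=records)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_captures_csv(path: str | Path, data: RobustDesignDataset) -> None:
    """Long-format capture CSV: one row per capture event (1-based indices)."""
    rows = []
    for rec in data.records:
        for t, k in zip(*np.nonzero(rec.encounters)):
            rows.append(
                {
                    "individual_id": rec.individual_id,
                    "patch_id": rec.patch_id,
                    "session": t + 1,
                    "occasion": k + 1,
                    "age": rec.age[t, k],
                    "sex": rec.sex or "",
                }
            )
    pd.DataFrame(
        rows,
        columns=["individual_id", "patch_id", "session", "occasion", "age", "sex"],
    ).to_csv(path, index=False)


def read_captures_csv(path: str | Path, design: StudyDesign) -> RobustDesignDataset:
    df = pd.read_csv(path, dtype={"individual_id": str, "patch_id": str})
    required = {"individual_id", "patch_id", "session", "occasion", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"capture CSV missing columns: {sorted(missing)}")
    T, K = design.n_primary, design.n_secondary
    records = []
    for ind_id, grp in df.groupby("individual_id", sort=False):
        enc = np.zeros((T, K), dtype=np.int8)
        age = np.full((T, K), None, dtype=object)
        patch = grp["patch_id"].iloc[0]
        if grp["patch_id"].nunique() != 1:
            raise ParseError(f"individual {ind_id!r} appears in multiple patches")
        for _, row in grp.iterrows():
            t, k = int(row["session"]) - 1, int(row["occasion"]) - 1
            if not (0 <= t < T and 0 <= k < K):
                raise ParseError(
                    f"individual {ind_id!r}: session/occasion out of design range"
                )
            enc[t, k] = 1
            age[t, k] = row["age"]
        sex = None
        if "sex" in grp.columns:
            s = grp["sex"].iloc[0]
            sex = None if pd.isna(s) or s == "" else str(s)
        records.append(EncounterRecord(str(ind_id), str(patch), enc, age, sex))
    return RobustDesignDataset(design=design, records=records)


def write_density_csv(path: str | Path, records: Iterable[DensityRecord]) -> None:
    pd.DataFrame(
        [
            {
                "patch_id": r.patch_id,
                "landscape": r.landscape_class,
                "area_ha": r.area_ha,
                "count": r.count,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_density_csv(path: str | Path) -> list[DensityRecord]:
    df = pd.read_csv(path, dtype={"patch_id": str})
    required = {"patch_id", "landscape", "area_ha", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"density CSV missing columns: {sorted(missing)}")
    return [
        DensityRecord(
            patch_id=str(row.patch_id),
            landscape_class=int(row.landscape),
            area_ha=float(row.area_ha),
            count=int(row.count),
        )
        for row in df.itertuples()
    ]


def study_design() -> StudyDesign:
    """The field protocol's design: 6 patches in two landscapes, 5 x 5
    robust design, 20-day intervals, 121 Sherman + 55 pitfall traps per grid."""
    return StudyDesign(
        n_primary=5,
        n_secondary=5,
        patches=(
            ("p1", 50), ("p2", 50), ("p3", 50),
            ("p4", 30), ("p5", 30), ("p6", 30),
        ),
        interval_days=20,
        trap_stations={"sherman": 121, "pitfall": 55},
    )
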