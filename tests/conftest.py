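"""Shared fixtures: small synthetic designs and datasets built in memory."""

import numpy as np
import pytest

from patchdemog import synthetic_data as sd
from patchdemog.capture_data import (
    ADULT,
    YOUNG,
    EncounterRecord,
    RobustDesignDataset,
    StudyDesign,
)


@pytest.fixture
def small_design() -> StudyDesign:
    return StudyDesign(
        n_primary=5,
        n_secondary=5,
        patches=(("A", 50), ("B", 30)),
    )


def make_record(
    individual_id: str,
    patch_id: str,
    captures: dict[tuple[int, int], str],
    shape: tuple[int, int] = (5, 5),
) -> EncounterRecord:
    """Build a record from {(session, occasion) 1-based: age} capture events."""
    enc = np.zeros(shape, dtype=np.int8)
    age = np.full(shape, None, dtype=object)
    for (t, k), a in captures.items():
        enc[t - 1, k - 1] = 1
        age[t - 1, k - 1] = a
    return EncounterRecord(individual_id, patch_id, enc, age)


@pytest.fixture
def mixed_age_dataset(small_design) -> RobustDesignDataset:
    """Six individuals covering young/adult transitions and both patches."""
    recs = [
        # young in session 1, adult later: adult captures must survive reduction
        make_record("i1", "A", {(1, 1): YOUNG, (3, 2): ADULT, (5, 5): ADULT}),
        # only ever young: dropped by reduction
        make_record("i2", "A", {(2, 3): YOUNG}),
        # adult throughout
        make_record("i3", "A", {(1, 2): ADULT, (1, 4): ADULT, (2, 1): ADULT}),
        make_record("i4", "B", {(4, 1): ADULT}),
        make_record("i5", "B", {(2, 2): ADULT, (4, 4): ADULT}),
        make_record("i6", "B", {(5, 3): YOUNG}),
    ]
    return RobustDesignDataset(design=small_design, records=recs)


def uniform_truth(
    n1: int = 40,
    phi: float = 0.6,
    imm_rate: float | None = None,
    young_rate: float = 0.0,
    p: float = 0.4,
    c: float = 0.4,
    n_patches: int = 6,
    T: int = 5,
    K: int = 5,
) -> sd.RDTruth:
    """Six identical patches; default immigration keeps lambda at 1."""
    if imm_rate is None:
        imm_rate = (1.0 - phi) * n1 - phi * young_rate
    patches = tuple(
        sd.PatchTruth(
            patch_id=f"p{i + 1}",
            landscape=50 if i < n_patches // 2 else 30,
            n1=n1,
            phi=phi,
            imm_rate=imm_rate,
            young_rate=young_rate,
        )
        for i in range(n_patches)
    )
    return sd.RDTruth(patches=patches, p=p, c=c, n_primary=T, n_secondary=K)
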