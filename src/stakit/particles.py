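"""Per-particle alignment state: poses, shifts, scores, class and half-set
labels, plus the table-backed container shared by all stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .volume import EulerTriplet


@dataclass
class ParticleRecord:
    """Alignment state of one subtomogram.

    ``position`` is the particle's location in the tomogram (Å);
    ``pose``/``shift`` map the reference onto the particle; ``cc`` is the
    last constrained cross-correlation score; ``halfset`` is 'A', 'B' or '-'
    before assignment.  ``shift_on_boundary`` flags a translation peak found
    at the search limit.
    """

    id: int
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pose: EulerTriplet = field(default_factory=EulerTriplet)
    shift: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cc: float = 0.0
    class_id: int = 0
    halfset: str = "-"
    shift_on_boundary: bool = False

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        if not -1.0 <= self.cc <= 1.0:
            raise ValueError(f"cc must lie in [-1, 1], got {self.cc}")


class ParticleSet:
    """Ordered collection of :class:`ParticleRecord` with table round-trip."""

    def __init__(self, records: list[ParticleRecord]):
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> ParticleRecord:
        return self.records[i]

    def copy(self) -> "ParticleSet":
        return ParticleSet(
            [
                replace(r, pose=r.pose, shift=r.shift.copy())
                for r in self.records
            ]
        )

    def assign_halfsets(self, seed: int) -> None:
        """Random seeded half-split; existing assignments are preserved."""
        unassigned = [r for r in self.records if r.halfset not in ("A", "B")]
        if not unassigned:
            return
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(unassigned))
        for rank, idx in enumerate(order):
            unassigned[idx].halfset = "A" if rank < len(order) / 2 else "B"

    def subset(self, indices) -> "ParticleSet":
        return ParticleSet([self.records[i] for i in indices])

    def halfset_indices(self, label: str) -> list[int]:
        return [i for i, r in enumerate(self.records) if r.halfset == label]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                dict(
                    id=r.id,
                    x=r.position[0],
                    y=r.position[1],
                    z=r.position[2],
                    tdrot=r.pose.tdrot,
                    tilt=r.pose.tilt,
                    narot=r.pose.narot,
                    dx=r.shift[0],
                    dy=r.shift[1],
                    dz=r.shift[2],
                    cc=r.cc,
                    class_id=r.class_id,
                    halfset=r.halfset,
                )
            )
        df = pd.DataFrame(rows, columns=sio.PARTICLE_COLUMNS)
        return sio.validate_particle_table(df) if len(df) else sio.empty_particle_table()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ParticleSet":
        df = sio.validate_particle_table(df)
        recs = [
            ParticleRecord(
                id=int(row.id),
                position=(row.x, row.y, row.z),
                pose=EulerTriplet(row.tdrot, row.tilt, row.narot),
                shift=np.array([row.dx, row.dy, row.dz]),
                cc=float(row.cc),
                class_id=int(row.class_id),
                halfset=str(row.halfset),
            )
            for row in df.itertuples()
        ]
        return cls(recs)

    def write(self, path: str | Path) -> None:
        sio.write_particle_table(self.to_dataframe(), path)

    @classmethod
    def read(cls, path: str | Path) -> "ParticleSet":
        return cls.from_dataframe(sio.read_particle_table(path))
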