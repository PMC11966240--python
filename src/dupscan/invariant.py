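"""Backbone rigid invariant (BRI) and its column average (Brain).

For a protein main-chain trace of ``m`` residues (atoms N, Cα, C per
residue), the BRI is an ``m × 9`` matrix: row ``i`` (``i ≥ 2``) holds the
coordinates of residue ``i``'s three trace atoms expressed in the local
frame of residue ``i − 1``; row 1 holds residue 1's own atoms in its own
frame, which forces the canonical zero pattern

    row 1 = (|N₁−Cα₁|, 0, 0,  0, 0, 0,  (C₁−Cα₁)·e1, (C₁−Cα₁)·e2, 0)

with the eighth entry strictly positive.  Columns are grouped per atom in
the order N, Cα, C, each as (x′, y′, z′).

The BRI is

* invariant under rigid motion (rotations + translations),
* complete: it can be inverted back to the backbone, unique up to rigid
  motion (:func:`reconstruct_backbone`),
* continuous: an ε-perturbation of the atoms moves every entry by O(ε),
* chirality-aware: a mirror image flips the sign of the z′ columns
  (:func:`mirror_bri`), so no mirror pair collides,
* hereditary: the rows of a contiguous subchain's BRI (beyond its first)
  equal the parent's rows exactly,

and it is computed in time linear in ``m``.  Averaging the nine columns
gives the 9-vector Brain, a cheap surrogate whose Chebyshev (L∞) distance
lower-bounds the Chebyshev distance of the full matrices — the inequality
the cascade prefilter rests on: a mean of absolute differences never
exceeds their maximum, column by column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ChainTooShort, DegenerateFrame, DimensionMismatch, InvalidRowOne
from .geometry import build_frame, express_in_frame, place_from_frame

#: BRI column labels, fixed so serialized invariants are comparable across runs
BRI_COLUMNS = (
    "N.x", "N.y", "N.z",
    "CA.x", "CA.y", "CA.z",
    "C.x", "C.y", "C.z",
)


@dataclass
class BackboneChain:
    """Ordered main-chain trace of one protein chain.

    ``n``, ``ca``, ``c`` are ``(m, 3)`` coordinate arrays in Å;
    ``residue_numbers`` must increase by exactly 1; ``aa_codes`` holds
    one-letter residue codes.
    """

    entry_id: str
    chain_id: str
    residue_numbers: np.ndarray
    aa_codes: list[str]
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.aa_codes = list(self.aa_codes)
        for name in ("n", "ca", "c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        self.validate()

    def validate(self):
        m = len(self.residue_numbers)
        if m < 2:
            raise ChainTooShort(f"{self.entry_id}:{self.chain_id} has {m} residue(s); need >= 2")
        if len(self.aa_codes) != m:
            raise ValueError("aa_codes length does not match residue count")
        for name in ("n", "ca", "c"):
            arr = getattr(self, name)
            if arr.shape != (m, 3):
                raise ValueError(f"{name} must have shape ({m}, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} has non-finite coordinates")
        if not np.all(np.diff(self.residue_numbers) == 1):
            raise ValueError("residue numbers must be consecutive integers")

    @property
    def m(self) -> int:
        """Residue count."""
        return len(self.residue_numbers)

    @property
    def label(self) -> str:
        return f"{self.entry_id}:{self.chain_id}"

    def atoms(self) -> np.ndarray:
        """All 3m trace atoms as a (3m, 3) array, residue-major, N/Cα/C order."""
        return np.stack([self.n, self.ca, self.c], axis=1).reshape(-1, 3)

    def with_coords(self, atoms: np.ndarray, entry_id: str | None = None,
                    chain_id: str | None = None) -> "BackboneChain":
        """Copy of the chain with coordinates replaced from a (3m, 3) array."""
        a = np.asarray(atoms, dtype=float).reshape(self.m, 3, 3)
        return BackboneChain(
            entry_id=entry_id if entry_id is not None else self.entry_id,
            chain_id=chain_id if chain_id is not None else self.chain_id,
            residue_numbers=self.residue_numbers.copy(),
            aa_codes=list(self.aa_codes),
            n=a[:, 0], ca=a[:, 1], c=a[:, 2],
        )

    def subchain(self, start: int, stop: int) -> "BackboneChain":
        """Contiguous residue slice [start, stop) by list position."""
        return BackboneChain(
            entry_id=self.entry_id,
            chain_id=self.chain_id,
            residue_numbers=self.residue_numbers[start:stop],
            aa_codes=self.aa_codes[start:stop],
            n=self.n[start:stop], ca=self.ca[start:stop], c=self.c[start:stop],
        )


@dataclass
class BRIMatrix:
    """The m×9 backbone rigid invariant, entries in Å."""

    entries: np.ndarray
    entry_id: str = ""
    chain_id: str = ""

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[1] != 9:
            raise ValueError(f"BRI must be m x 9, got {self.entries.shape}")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("BRI has non-finite entries")

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    def validate_row_one(self, atol: float = 0.0):
        """Check the canonical first-row zero pattern (columns 2,3,4,5,6,9)."""
        r = self.entries[0]
        zeros = r[[1, 2, 3, 4, 5, 8]]
        if np.any(np.abs(zeros) > atol):
            raise InvalidRowOne("row 1 violates the canonical zero pattern")
        if r[0] <= 0 or r[7] <= 0:
            raise InvalidRowOne("row 1 requires |N1-CA1| > 0 and (C1-CA1).e2 > 0")


@dataclass
class BrainVector:
    """Columnwise mean of a BRI matrix: nine coordinates in Å."""

    entries: np.ndarray
    entry_id: str = ""
    chain_id: str = ""
    m: int = 0

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (9,):
            raise ValueError(f"Brain must have 9 entries, got {self.entries.shape}")


def _frame_bases(chain: BackboneChain) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal bases (m,3,3; rows e1,e2,e3) and origins for every residue.

    Vectorized equivalent of calling :func:`~dupscan.geometry.build_frame`
    per residue; raises DegenerateFrame with the 1-based residue index.
    """
    u = chain.n - chain.ca
    v = chain.c - chain.ca
    w = np.cross(u, v)
    wn = np.linalg.norm(w, axis=1)
    bad = np.nonzero(wn <= 1e-6)[0]
    if bad.size:
        raise DegenerateFrame(
            f"degenerate frame at residue index {bad[0] + 1} of {chain.label}",
            residue_index=int(bad[0] + 1),
        )
    e1 = u / np.linalg.norm(u, axis=1)[:, None]
    e3 = w / wn[:, None]
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=1), chain.ca


def compute_bri(chain: BackboneChain) -> BRIMatrix:
    """Compute the backbone rigid invariant of a chain (O(m) time)."""
    bases, origins = _frame_bases(chain)
    m = chain.m
    out = np.empty((m, 9))
    # rows 2..m: residue i atoms in the frame of residue i-1
    prev_b = bases[:-1]          # (m-1, 3, 3)
    prev_o = origins[:-1]        # (m-1, 3)
    for j, atom in enumerate((chain.n, chain.ca, chain.c)):
        d = atom[1:] - prev_o    # (m-1, 3)
        out[1:, 3 * j:3 * j + 3] = np.einsum("ikj,ij->ik", prev_b, d)
    # row 1: residue 1 in its own frame
    d_n = chain.n[0] - origins[0]
    d_c = chain.c[0] - origins[0]
    b0 = bases[0]
    out[0] = [
        float(np.linalg.norm(d_n)), 0.0, 0.0,
        0.0, 0.0, 0.0,
        float(d_c @ b0[0]), float(d_c @ b0[1]), 0.0,
    ]
    return BRIMatrix(out, entry_id=chain.entry_id, chain_id=chain.chain_id)


def compute_brain(bri: BRIMatrix) -> BrainVector:
    """Average the nine BRI columns (all rows weighted equally)."""
    return BrainVector(
        bri.entries.mean(axis=0),
        entry_id=bri.entry_id,
        chain_id=bri.chain_id,
        m=bri.m,
    )


def bri_distance(a: BRIMatrix, b: BRIMatrix) -> float:
    """Chebyshev (L∞) distance between two BRI matrices of equal m, in Å."""
    if a.entries.shape != b.entries.shape:
        raise DimensionMismatch(
            f"BRI shapes differ: {a.entries.shape} vs {b.entries.shape}"
        )
    return float(np.max(np.abs(a.entries - b.entries)))


def brain_distance(a: BrainVector, b: BrainVector) -> float:
    """Chebyshev (L∞) distance between two Brain vectors, in Å.

    For chains of equal length this never exceeds :func:`bri_distance` of
    the full matrices — the lower bound that makes the Brain prefilter
    lossless.
    """
    return float(np.max(np.abs(a.entries - b.entries)))


def reconstruct_backbone(bri: BRIMatrix) -> BackboneChain:
    """Invert a BRI back to backbone coordinates in the canonical pose.

    Residue 1 is placed from row 1 (Cα₁ at the origin, N₁ on +x, C₁ in the
    xy-plane with positive y); each later residue is placed in the frame
    built on the previously reconstructed residue.  Residue codes are set
    to 'X' and numbering to 1..m: the invariant stores geometry only.
    """
    bri.validate_row_one(atol=0.0)
    m = bri.m
    e = bri.entries
    n = np.empty((m, 3))
    ca = np.empty((m, 3))
    c = np.empty((m, 3))
    ca[0] = (0.0, 0.0, 0.0)
    n[0] = (e[0, 0], 0.0, 0.0)
    c[0] = (e[0, 6], e[0, 7], 0.0)
    for i in range(1, m):
        try:
            frame = build_frame(n[i - 1], ca[i - 1], c[i - 1])
        except DegenerateFrame as err:
            raise DegenerateFrame(
                f"degenerate frame while rebuilding residue {i + 1}", residue_index=i + 1
            ) from err
        n[i] = place_from_frame(e[i, 0:3], frame)
        ca[i] = place_from_frame(e[i, 3:6], frame)
        c[i] = place_from_frame(e[i, 6:9], frame)
    return BackboneChain(
        entry_id=bri.entry_id or "RECON",
        chain_id=bri.chain_id or "A",
        residue_numbers=np.arange(1, m + 1),
        aa_codes=["X"] * m,
        n=n, ca=ca, c=c,
    )


def mirror_bri(bri: BRIMatrix) -> BRIMatrix:
    """BRI of the point-reflected chain.

    Reflection flips the handedness of every residue frame (e3 reverses),
    so the z′ columns change sign for rows ≥ 2; row 1's chirality-bearing
    entries are structurally zero and stay put.
    """
    out = bri.entries.copy()
    out[1:, [2, 5, 8]] *= -1.0
    return BRIMatrix(out, entry_id=bri.entry_id, chain_id=bri.chain_id)


def write_bri_tsv(bri: BRIMatrix, path: str | Path | io.TextIOBase) -> None:
    """Serialize a BRI as TSV: #entry/#chain/#m comments, header, 6 decimals."""
    def _dump(fh):
        fh.write(f"#entry\t{bri.entry_id}\n")
        fh.write(f"#chain\t{bri.chain_id}\n")
        fh.write(f"#m\t{bri.m}\n")
        fh.write("\t".join(BRI_COLUMNS) + "\n")
        for row in bri.entries:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")

    if isinstance(path, io.TextIOBase):
        _dump(path)
    else:
        with open(path, "w") as fh:
            _dump(fh)


def read_bri_tsv(path: str | Path) -> BRIMatrix:
    """Read a BRI serialized by :func:`write_bri_tsv`."""
    entry_id = chain_id = ""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#entry"):
                entry_id = line.split("\t", 1)[1] if "\t" in line else ""
            elif line.startswith("#chain"):
                chain_id = line.split("\t", 1)[1] if "\t" in line else ""
            elif line.startswith("#") or line.startswith("N.x"):
                continue
            elif line:
                rows.append([float(v) for v in line.split("\t")])
    return BRIMatrix(np.array(rows), entry_id=entry_id, chain_id=chain_id)
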