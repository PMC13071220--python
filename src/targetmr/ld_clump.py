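"""LD-matrix handling and greedy p-value-ordered clumping.

Clumping implements the standard independence filter used in instrument
selection: candidates are ranked by ascending p-value, the best remaining
variant is retained, and every remaining variant on the same chromosome
within the window and with r-squared at or above the threshold is removed
to that index variant.  The reference defaults mirror common practice for
two-sample MR (r² < 0.001 within a 10 000 kb window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class LDMatrix:
    """Squared-correlation matrix over an ordered set of variants."""

    variant_ids: list[str]
    chroms: list[str]
    positions: list[int]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValidationError(
                f"r2 shape {self.r2.shape} does not match {k} variants"
            )
        if len(set(self.variant_ids)) != k:
            raise ValidationError("variant_ids must be unique")
        if len(self.chroms) != k or len(self.positions) != k:
            raise ValidationError("chroms/positions must align with variant_ids")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise ValidationError(f"variant {variant_id!r} absent from LD matrix")

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self.index_of(a), self.index_of(b)])


@dataclass
class ClumpResult:
    """Variants retained by clumping; removed maps variant -> its index SNP."""

    retained: list[str] = field(default_factory=list)
    removed: dict[str, str] = field(default_factory=dict)


def validate_ld_matrix(ld: LDMatrix, atol: float = 1e-8) -> list[str]:
    """List violations of symmetry, [0, 1] range and unit diagonal.

    An empty report means the matrix is a valid r² matrix.
    """
    report: list[str] = []
    r2 = ld.r2
    diag = np.diag(r2)
    for i in np.nonzero(np.abs(diag - 1.0) > atol)[0]:
        report.append(f"diagonal not 1 at {ld.variant_ids[i]} ({diag[i]:.6g})")
    bad = np.argwhere((r2 < -atol) | (r2 > 1 + atol))
    for i, j in bad:
        report.append(
            f"entry out of [0,1] at ({ld.variant_ids[i]}, {ld.variant_ids[j]}): "
            f"{r2[i, j]:.6g}"
        )
    asym = np.argwhere(np.abs(r2 - r2.T) > atol)
    seen = set()
    for i, j in asym:
        if (j, i) in seen or i == j:
            continue
        seen.add((i, j))
        report.append(
            f"asymmetry between indices ({i}, {j}): "
            f"{r2[i, j]:.6g} vs {r2[j, i]:.6g}"
        )
    return report


def clump(
    candidates: list[tuple[str, float]],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> ClumpResult:
    """Greedy p-value-ordered clumping.

    Ties on p are broken by smaller position, then lexicographic variant
    ID, so output is deterministic.  The window is measured between ``pos``
    values, inclusive, and only variants on the same chromosome are ever
    clumped together.  A candidate missing from ``ld`` is an error rather
    than being silently assumed independent.
    """
    for vid, _ in candidates:
        ld.index_of(vid)

    window_bp = window_kb * 1000.0
    order = sorted(
        candidates,
        key=lambda c: (c[1], ld.positions[ld.index_of(c[0])], c[0]),
    )
    result = ClumpResult()
    alive = {vid for vid, _ in candidates}
    for vid, _p in order:
        if vid not in alive:
            continue
        alive.discard(vid)
        result.retained.append(vid)
        i = ld.index_of(vid)
        for other in list(alive):
            j = ld.index_of(other)
            if ld.chroms[i] != ld.chroms[j]:
                continue
            if abs(ld.positions[i] - ld.positions[j]) > window_bp:
                continue
            if ld.r2[i, j] >= r2_threshold:
                alive.discard(other)
                result.removed[other] = vid
    return result


def write_ld_matrix(ld: LDMatrix, matrix_path: str | Path, sidecar_path: str | Path) -> None:
    """Write the square r² matrix (IDs as header row/column) and sidecar."""
    df = pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids)
    df.to_csv(matrix_path, sep="\t", index_label="variant_id")
    side = pd.DataFrame(
        {"variant_id": ld.variant_ids, "chrom": ld.chroms, "pos": ld.positions}
    )
    side.to_csv(sidecar_path, sep="\t", index=False)


def read_ld_matrix(matrix_path: str | Path, sidecar_path: str | Path) -> LDMatrix:
    """Read the matrix/sidecar pair written by :func:`write_ld_matrix`."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    side = pd.read_csv(sidecar_path, sep="\t", dtype={"chrom": str})
    side = side.set_index("variant_id").loc[df.index]
    return LDMatrix(
        variant_ids=[str(v) for v in df.index],
        chroms=[str(c) for c in side["chrom"]],
        positions=[int(p) for p in side["pos"]],
        r2=df.to_numpy(dtype=float),
    )
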