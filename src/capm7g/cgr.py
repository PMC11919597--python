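"""Chaos game representation (CGR) and its frequency-matrix form (FCGR).

A sequence s1..sn is mapped onto the open square (-1,1)^2 by iterated
midpoints: starting from the origin, each base moves the current point
halfway toward its corner,

    (x_i, y_i) = ((x_{i-1}, y_{i-1}) + h(s_i)) / 2,

with corners h(A)=(-1,1), h(U)=(1,1), h(C)=(-1,-1), h(G)=(1,-1). Each CGR
point encodes the full prefix history; binning points on a 2^k x 2^k grid
(the FCGR) turns the trajectory into a k-mer-suffix count matrix that is
rendered as a grayscale image for the classifier.

Conventions (fixed; golden tests pin them):

* rows index y from top (row 0 = y near +1), columns index x from left
  (col 0 = x near -1), so A is top-left, U top-right, C bottom-left and
  G bottom-right;
* ALL n trajectory points are binned, including the first k-1 whose cells
  reflect shorter prefixes, so counts always sum to the sequence length;
* cells are half-open, a coordinate exactly on an interior edge belongs to
  the higher-index cell (coordinates never reach the outer edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import RnaWindow

#: corner assignment for each base, per the iterated-midpoint map
CGR_VERTICES = {
    "A": (-1.0, 1.0),
    "U": (1.0, 1.0),
    "C": (-1.0, -1.0),
    "G": (1.0, -1.0),
}

DEFAULT_GRID_SIZE = 64

_VERTEX_X = np.zeros(256)
_VERTEX_Y = np.zeros(256)
for _base, (_vx, _vy) in CGR_VERTICES.items():
    _VERTEX_X[ord(_base)] = _vx
    _VERTEX_Y[ord(_base)] = _vy


@dataclass
class CgrTrajectory:
    """Ordered CGR points of one sequence; ``points`` has shape (n, 2)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class FcgrImage:
    """FCGR count matrix and its max-scaled grayscale form.

    ``counts[r, c]`` is the number of trajectory points falling in grid
    cell (row r, col c); ``normalized`` is counts / counts.max() (all
    zeros if the matrix is empty), so pixels lie in [0, 1].
    """

    counts: np.ndarray
    grid_size: int
    normalized: np.ndarray
    source_length: int


def cgr_encode(window: RnaWindow | str) -> CgrTrajectory:
    """Run the iterated-midpoint map over a canonical sequence."""
    seq = window.sequence if isinstance(window, RnaWindow) else window
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    vx = _VERTEX_X[codes]
    vy = _VERTEX_Y[codes]
    n = len(seq)
    # x_i = sum_{t<=i} h_x(s_t) / 2^(i-t+1); evaluate the recurrence directly
    pts = np.empty((n, 2))
    x = y = 0.0
    for i in range(n):
        x = 0.5 * (x + vx[i])
        y = 0.5 * (y + vy[i])
        pts[i, 0] = x
        pts[i, 1] = y
    return CgrTrajectory(pts)


def fcgr_encode(
    trajectory: CgrTrajectory, grid_size: int = DEFAULT_GRID_SIZE
) -> FcgrImage:
    """Bin a CGR trajectory onto a grid_size x grid_size count matrix."""
    n = grid_size
    if n < 1 or (n & (n - 1)) != 0:
        raise ValueError(f"grid_size must be a power of 2, got {n}")
    pts = trajectory.points
    if len(pts) == 0:
        raise ValueError("empty trajectory")
    # half-open binning: floor((x+1)/2 * N); x,y in (-1,1) so indices in [0, N)
    cols = np.floor((pts[:, 0] + 1.0) / 2.0 * n).astype(np.intp)
    rows_from_bottom = np.floor((pts[:, 1] + 1.0) / 2.0 * n).astype(np.intp)
    rows = n - 1 - rows_from_bottom  # row 0 = top (y near +1)
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (rows, cols), 1)
    cmax = counts.max()
    normalized = counts / cmax if cmax > 0 else np.zeros_like(counts, dtype=float)
    return FcgrImage(
        counts=counts,
        grid_size=n,
        normalized=normalized.astype(np.float64),
        source_length=len(pts),
    )


def encode_window(window: RnaWindow | str, grid_size: int = DEFAULT_GRID_SIZE) -> FcgrImage:
    """Sequence -> CGR -> FCGR in one step."""
    return fcgr_encode(cgr_encode(window), grid_size)


def encode_windows(windows, grid_size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Stack normalized FCGR images of many windows into (n, grid, grid)."""
    return np.stack([encode_window(w, grid_size).normalized for w in windows])


def kmer_cell(kmer: str, grid_size: int) -> tuple[int, int]:
    """Grid cell whose suffix set is exactly ``kmer`` (len(kmer) = log2 N).

    The FCGR cell of trajectory point i depends only on the last k bases;
    this computes that cell arithmetically, independent of the recurrence.
    """
    k = int(np.log2(grid_size))
    if len(kmer) != k:
        raise ValueError(f"kmer length must be log2(grid_size) = {k}")
    x = y = 0.0
    for base in kmer:
        vx, vy = CGR_VERTICES[base]
        x = 0.5 * (x + vx)
        y = 0.5 * (y + vy)
    # after k steps from anywhere in (-1,1)^2 the point lies in a unique cell
    col = int(np.floor((x + 1.0) / 2.0 * grid_size))
    row = grid_size - 1 - int(np.floor((y + 1.0) / 2.0 * grid_size))
    return row, col
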