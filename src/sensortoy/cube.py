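"""Surface geometry of the sensor-augmented play cube.

The toy is a cube with a 3x3 grid of LED cells on each of its six faces,
54 cells in total, addressed by a single index ``i`` in ``{0, ..., 53}``.
Games move a highlighted dot across this surface, so the package needs a
topological model of the surface grid (which cell lies "forward" of which,
what turning left or right means, what happens when the dot rolls over an
edge onto the neighbouring face) and a geometric model (a direction vector
per cell, so that "how close is this cell to the top of the cube" is a
cosine).

Index layout (a fixed, documented convention — the physical toy's layout is
not public): cells are face-major, face ``f`` owning indices ``9f .. 9f+8``,
row-major within the face as seen from outside the cube.  Faces are ordered
by outward normal ``(+z, +x, -z, -x, +y, -y)``.  Each face carries a column
axis ``u`` and a row axis ``v``; cell (row r, col c) sits at grid position
``1.5*n + (c-1)*u + (1-r)*v`` on a cube of side 3 centred at the origin.

Headings are in-face unit steps, represented as integer 3-vectors tangent to
the current face.  Crossing an edge re-expresses the heading in the next
face's basis: the new face's normal is the old heading, the new heading is
the old normal negated (the dot "rolls" over the edge).

All arithmetic below is exact integer arithmetic on doubled grid
coordinates; floating point appears only in the normalised centre vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

N_FACES = 6
CELLS_PER_FACE = 9
N_CELLS = N_FACES * CELLS_PER_FACE

#: face id -> (outward normal n, column axis u, row axis v), integer unit vectors
FACE_FRAMES: tuple[tuple[tuple[int, int, int], tuple[int, int, int], tuple[int, int, int]], ...] = (
    ((0, 0, 1), (1, 0, 0), (0, 1, 0)),    # face 0: +z
    ((1, 0, 0), (0, 1, 0), (0, 0, 1)),    # face 1: +x
    ((0, 0, -1), (1, 0, 0), (0, -1, 0)),  # face 2: -z
    ((-1, 0, 0), (0, 1, 0), (0, 0, -1)),  # face 3: -x
    ((0, 1, 0), (0, 0, 1), (1, 0, 0)),    # face 4: +y
    ((0, -1, 0), (0, 0, 1), (-1, 0, 0)),  # face 5: -y
)

Vec3 = tuple[int, int, int]


def _add(a: Vec3, b: Vec3, k: int = 1) -> Vec3:
    return (a[0] + k * b[0], a[1] + k * b[1], a[2] + k * b[2])


def _neg(a: Vec3) -> Vec3:
    return (-a[0], -a[1], -a[2])


def _cross(a: Vec3, b: Vec3) -> Vec3:
    return (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )


@dataclass(frozen=True)
class CubeTopology:
    """The fixed 54-cell surface grid of the toy.

    Instances are built by :func:`build_topology`; the class only carries
    precomputed lookup tables and exposes queries over them.
    """

    #: doubled grid coordinates of each cell centre, shape (54, 3), int
    grid: np.ndarray
    #: unit centre directions, shape (54, 3), float
    centers: np.ndarray
    #: map doubled-grid tuple -> cell index
    _index_of: dict[Vec3, int]

    # -- structure ---------------------------------------------------------

    def face_of(self, cell: int) -> int:
        self._check_cell(cell)
        return cell // CELLS_PER_FACE

    def middle_cell(self, face: int) -> int:
        """The centre cell (row 1, col 1) of a face."""
        if not 0 <= face < N_FACES:
            raise ValueError(f"face id out of range: {face}")
        return face * CELLS_PER_FACE + 4

    def is_middle(self, cell: int) -> bool:
        self._check_cell(cell)
        return cell % CELLS_PER_FACE == 4

    def face_normal(self, face: int) -> np.ndarray:
        if not 0 <= face < N_FACES:
            raise ValueError(f"face id out of range: {face}")
        return np.array(FACE_FRAMES[face][0], dtype=float)

    def cell_center(self, cell: int) -> np.ndarray:
        """Unit vector from the cube centre through the cell centre (body frame)."""
        self._check_cell(cell)
        return self.centers[cell]

    def headings(self, cell: int) -> tuple[Vec3, Vec3, Vec3, Vec3]:
        """The four in-face travel directions available at ``cell``."""
        _, u, v = FACE_FRAMES[self.face_of(cell)]
        return (u, _neg(u), v, _neg(v))

    # -- movement ----------------------------------------------------------

    def forward(self, cell: int, heading: Vec3) -> tuple[int, Vec3]:
        """One forward step from ``(cell, heading)``.

        Within a face this is a plain grid step; over an edge the dot rolls
        onto the adjacent face and the heading becomes the old face normal,
        negated.  The map is a bijection on the 216 (cell, heading) states.
        """
        g = tuple(int(x) for x in self.grid[cell])
        n = FACE_FRAMES[self.face_of(cell)][0]
        self._check_heading(cell, heading)
        candidate = _add(g, heading, 2)
        if candidate in self._index_of:
            return self._index_of[candidate], heading
        # roll over the edge: new face normal = heading, new heading = -n
        landed = _add(_add(g, heading), _neg(n))
        return self._index_of[landed], _neg(n)

    def turn_left(self, cell: int, heading: Vec3) -> Vec3:
        """Rotate the heading 90° counter-clockwise about the face normal."""
        n = FACE_FRAMES[self.face_of(cell)][0]
        self._check_heading(cell, heading)
        return _cross(n, heading)

    def turn_right(self, cell: int, heading: Vec3) -> Vec3:
        n = FACE_FRAMES[self.face_of(cell)][0]
        self._check_heading(cell, heading)
        return _cross(heading, n)

    def neighbors(self, cell: int) -> tuple[int, int, int, int]:
        """The four distinct forward-neighbours of a cell (one per heading)."""
        return tuple(self.forward(cell, h)[0] for h in self.headings(cell))

    def are_adjacent(self, a: int, b: int) -> bool:
        return b in self.neighbors(a)

    # -- orientation-dependent queries --------------------------------------

    def alignment(self, cell: int, up_body: np.ndarray, *, tol: float = 1e-6) -> float:
        """Cosine between the cell's centre direction and the body-frame up.

        ``up_body`` is the world up direction expressed in the cube body
        frame and must be a unit vector.  1 means the cell points straight
        up, -1 straight down.
        """
        up = np.asarray(up_body, dtype=float)
        nrm = np.linalg.norm(up)
        if abs(nrm - 1.0) > tol:
            raise ValueError(f"up_body must be a unit vector (norm={nrm:.6g})")
        return float(np.clip(self.cell_center(cell) @ up, -1.0, 1.0))

    def up_face(self, orientation: Rotation, *, tol: float = 1e-9) -> int:
        """Face whose outward normal points most nearly up in the world frame.

        ``orientation`` maps body coordinates to world coordinates.  Exact
        ties (e.g. a 45° pose) resolve to the lowest face id.
        """
        normals = np.array([f[0] for f in FACE_FRAMES], dtype=float)
        z = orientation.apply(normals)[:, 2]
        best = float(np.max(z))
        return int(np.nonzero(z >= best - tol)[0][0])

    # -- internals ----------------------------------------------------------

    def _check_cell(self, cell: int) -> None:
        if not 0 <= cell < N_CELLS:
            raise ValueError(f"cell index out of range: {cell}")

    def _check_heading(self, cell: int, heading: Vec3) -> None:
        if tuple(heading) not in self.headings(cell):
            raise ValueError(f"heading {heading} is not tangent to the face of cell {cell}")


def build_topology() -> CubeTopology:
    """Construct the fixed cube-surface topology under the documented layout."""
    grid = np.zeros((N_CELLS, 3), dtype=int)
    index_of: dict[Vec3, int] = {}
    for face, (n, u, v) in enumerate(FACE_FRAMES):
        for r in range(3):
            for c in range(3):
                cell = face * CELLS_PER_FACE + 3 * r + c
                g = _add(_add(tuple(3 * x for x in n), u, 2 * (c - 1)), v, 2 * (1 - r))
                grid[cell] = g
                index_of[g] = cell
    centers = grid / np.linalg.norm(grid, axis=1, keepdims=True)
    return CubeTopology(grid=grid, centers=centers, _index_of=index_of)
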