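"""Organized point clouds and PCD file I/O.

A time-of-flight camera delivers, besides its mono (amplitude) image, one 3D
point per pixel. Stored row-major, pixel ``(u, v)`` of the mono image and
entry ``v * width + u`` of the cloud describe the same scene point — this
internal registration is what makes the ToF camera usable as a geometric
bridge between the thermal and RGB cameras. Invalid measurements (dropouts,
out-of-range) are NaN entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NoDepthError

__all__ = ["OrganizedPointCloud", "read_pcd", "write_pcd"]


@dataclass
class OrganizedPointCloud:
    """ToF point cloud indexable by mono-image pixel.

    ``points`` has shape ``(height, width, 3)`` in meters, expressed in the
    ToF camera frame; NaN rows mark invalid pixels.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise InvalidInputError("organized cloud must have shape (H, W, 3)")

    @property
    def height(self) -> int:
        return self.points.shape[0]

    @property
    def width(self) -> int:
        return self.points.shape[1]

    @property
    def finite_mask(self) -> np.ndarray:
        """(H, W) boolean mask of pixels carrying a valid 3D point."""
        return np.all(np.isfinite(self.points), axis=2)

    def flat(self) -> np.ndarray:
        """Row-major ``(H*W, 3)`` view of the points."""
        return self.points.reshape(-1, 3)

    def lookup(self, u: int, v: int) -> np.ndarray:
        """3D point at integer mono-image pixel ``(u, v)``.

        Raises
        ------
        IndexError
            Pixel outside the mono image.
        NoDepthError
            The entry exists but is not finite (measurement dropout).
        """
        u, v = int(u), int(v)
        if not (0 <= u < self.width and 0 <= v < self.height):
            raise IndexError(f"pixel ({u}, {v}) outside {self.width}x{self.height}")
        p = self.points[v, u]
        if not np.all(np.isfinite(p)):
            raise NoDepthError(f"no valid depth at pixel ({u}, {v})")
        return p.copy()


def write_pcd(cloud: OrganizedPointCloud, path) -> None:
    """Write an organized cloud as ASCII PCD (WIDTH/HEIGHT honored)."""
    pts = cloud.flat()
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        "FIELDS x y z\n"
        "SIZE 4 4 4\n"
        "TYPE F F F\n"
        "COUNT 1 1 1\n"
        f"WIDTH {cloud.width}\n"
        f"HEIGHT {cloud.height}\n"
        "VIEWPOINT 0 0 0 1 0 0 0\n"
        f"POINTS {pts.shape[0]}\n"
        "DATA ascii\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for x, y, z in pts:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def read_pcd(path) -> OrganizedPointCloud:
    """Read an organized PCD file (ASCII or binary, x/y/z float32/float64).

    The WIDTH/HEIGHT header is honored; a HEIGHT of 1 (unorganized cloud)
    is rejected because downstream pixel lookup requires organization.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    # header is ASCII up to and including the DATA line
    end = raw.find(b"DATA")
    if end < 0:
        raise InvalidInputError("not a PCD file: missing DATA line")
    newline = raw.find(b"\n", end)
    header_text = raw[: newline + 1].decode("ascii", errors="replace")
    body = raw[newline + 1 :]

    meta: dict[str, list[str]] = {}
    for line in header_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, *vals = line.split()
        meta[key.upper()] = vals

    for req in ("FIELDS", "WIDTH", "HEIGHT", "DATA"):
        if req not in meta:
            raise InvalidInputError(f"PCD header missing {req}")
    fields = [f.lower() for f in meta["FIELDS"]]
    if fields[:3] != ["x", "y", "z"]:
        raise InvalidInputError("PCD must start with x y z fields")
    width = int(meta["WIDTH"][0])
    height = int(meta["HEIGHT"][0])
    if height <= 1:
        raise InvalidInputError("cloud is not organized (HEIGHT must exceed 1)")
    n = width * height
    mode = meta["DATA"][0].lower()

    if mode == "ascii":
        data = np.loadtxt(body.decode("ascii").splitlines(), dtype=float, ndmin=2)
        if data.shape[0] != n:
            raise InvalidInputError(
                f"expected {n} points, file holds {data.shape[0]}"
            )
        xyz = data[:, :3]
    elif mode == "binary":
        sizes = [int(s) for s in meta.get("SIZE", ["4"] * len(fields))]
        types = meta.get("TYPE", ["F"] * len(fields))
        np_types = []
        for s, t in zip(sizes, types):
            code = {"F": "f", "I": "i", "U": "u"}[t.upper()]
            np_types.append(f"{code}{s}")
        dtype = np.dtype({"names": fields, "formats": np_types})
        rec = np.frombuffer(body[: n * dtype.itemsize], dtype=dtype)
        if rec.shape[0] != n:
            raise InvalidInputError("binary PCD body shorter than WIDTH*HEIGHT")
        xyz = np.stack(
            [rec["x"].astype(float), rec["y"].astype(float), rec["z"].astype(float)],
            axis=1,
        )
    else:
        raise InvalidInputError(f"unsupported PCD DATA mode: {mode}")

    return OrganizedPointCloud(xyz.reshape(height, width, 3))
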