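"""File formats: TIFF images, HDF5 light-field containers, CSV/JSON tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .calibration import CalibrationResult
from .decode import EPI, LightField4D
from .dictionary import EPIDictionary

__all__ = [
    "read_image", "write_image", "save_lightfield", "load_lightfield",
    "save_calibration", "load_calibration", "save_dictionary_pair",
    "load_dictionary_pair", "write_locations_csv", "read_locations_csv",
]


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_image(path: str | Path, image: np.ndarray,
                dtype: str = "float32") -> None:
    tifffile.imwrite(path, np.asarray(image).astype(dtype))


def save_lightfield(path: str | Path, lf: LightField4D,
                    epi_h: EPI | None = None, epi_v: EPI | None = None) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("lf4d", data=lf.data)
        ds.attrs["axes"] = "i,j,k,l (angular row/col, lenslet row/col)"
        if lf.edge_flags is not None:
            fh.create_dataset("edge_flags", data=lf.edge_flags)
        for name, epi in (("horizontal", epi_h), ("vertical", epi_v)):
            if epi is not None:
                d = fh.create_dataset(f"epi/{name}", data=epi.data)
                d.attrs["axes"] = "angular,spatial"
                d.attrs["fixed_indices"] = list(epi.fixed_indices)


def load_lightfield(path: str | Path
                    ) -> tuple[LightField4D, EPI | None, EPI | None]:
    with h5py.File(path, "r") as fh:
        lf = LightField4D(fh["lf4d"][()],
                          fh["edge_flags"][()] if "edge_flags" in fh else None)
        epis = {}
        for name in ("horizontal", "vertical"):
            key = f"epi/{name}"
            if key in fh:
                epis[name] = EPI(fh[key][()], name,
                                 tuple(int(v) for v in
                                       fh[key].attrs["fixed_indices"]))
    return lf, epis.get("horizontal"), epis.get("vertical")


def save_calibration(path: str | Path, calib: CalibrationResult) -> None:
    with open(path, "w") as fh:
        json.dump({"rotation_angle_deg": calib.rotation_angle_deg,
                   "pitch_px": calib.pitch_px,
                   "centers": calib.centers.tolist()}, fh, indent=1)


def load_calibration(path: str | Path) -> CalibrationResult:
    with open(path) as fh:
        d = json.load(fh)
    return CalibrationResult(d["rotation_angle_deg"], d["pitch_px"],
                             np.asarray(d["centers"]))


def save_dictionary_pair(path: str | Path, dict_h: EPIDictionary,
                         dict_v: EPIDictionary) -> None:
    import json as _json
    with h5py.File(path, "w") as fh:
        for name, dic in (("horizontal", dict_h), ("vertical", dict_v)):
            g = fh.create_group(name)
            g.create_dataset("atoms", data=dic.atoms)
            g.create_dataset("depths", data=dic.depths_um)
            g.attrs["anchor_col"] = dic.anchor_col
            g.attrs["ball_diameter_um"] = dic.ball_diameter_um
            g.attrs["optical_config"] = _json.dumps(dic.config.to_dict())


def load_dictionary_pair(path: str | Path
                         ) -> tuple[EPIDictionary, EPIDictionary]:
    import json as _json
    from .config import OpticalConfig
    out = []
    with h5py.File(path, "r") as fh:
        for name in ("horizontal", "vertical"):
            g = fh[name]
            out.append(EPIDictionary(
                atoms=g["atoms"][()], depths_um=g["depths"][()],
                orientation=name, anchor_col=int(g.attrs["anchor_col"]),
                config=OpticalConfig.from_dict(
                    _json.loads(g.attrs["optical_config"])),
                ball_diameter_um=float(g.attrs["ball_diameter_um"])))
    return out[0], out[1]


_CSV_HEADER = "source_id,x_um,y_um,z_um,w_h,w_v,atom_index_h,atom_index_v"


def write_locations_csv(path: str | Path, result) -> None:
    lines = [_CSV_HEADER]
    for s, p in enumerate(result.positions):
        lines.append(f"{s},{p[0]:.4f},{p[1]:.4f},{p[2]:.4f},"
                     f"{result.w_h:.6f},{result.w_v:.6f},"
                     f"{result.omega_h[s]},{result.omega_v[s]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_locations_csv(path: str | Path) -> np.ndarray:
    rows = Path(path).read_text().strip().splitlines()[1:]
    return np.array([[float(v) for v in r.split(",")[1:4]] for r in rows])
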