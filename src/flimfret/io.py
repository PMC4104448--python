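"""File formats and run configuration.

FLIM stacks travel either as multi-page TIFF (one spatial page per time
channel, acquisition metadata as a JSON image description) or as a single
HDF5 file (counts dataset + attributes; ground-truth maps, when present,
survive only the HDF5 route). Decay histograms and binding series are
plain delimited text with headers. Every reader validates and reports the
offending line or missing key rather than returning a partial object.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .sim import BindingSeries, FLIMStack
from .tcspc import IRFSpec, TCSPCConfig

__all__ = [
    "FormatError",
    "RunConfig",
    "read_flim_stack",
    "write_flim_stack",
    "read_decay_table",
    "write_decay_table",
    "read_binding_table",
    "write_binding_table",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# FLIM stacks


def _irf_to_dict(irf: IRFSpec) -> dict:
    if irf.kind == "tabulated":
        return {"kind": "tabulated", "counts": np.asarray(irf.counts).tolist()}
    return {"kind": "gaussian", "center": irf.center, "fwhm": irf.fwhm}


def _irf_from_dict(d: dict) -> IRFSpec:
    if "kind" not in d:
        raise FormatError("IRF metadata missing required key 'kind'")
    if d["kind"] == "tabulated":
        return IRFSpec(kind="tabulated", counts=np.asarray(d["counts"], dtype=float))
    return IRFSpec(kind="gaussian", center=float(d["center"]), fwhm=float(d["fwhm"]))


_REQUIRED_META = ("channel_width", "n_channels", "analysis_channels", "irf")


def write_flim_stack(stack: FLIMStack, path: str | Path) -> None:
    """Write a FLIM stack to ``.tif/.tiff`` or ``.h5/.hdf5`` by suffix.

    Counts and acquisition metadata round-trip bit-exactly through both
    containers; truth maps and provenance round-trip through HDF5 only.
    """
    path = Path(path)
    meta = {
        "channel_width": stack.config.channel_width,
        "n_channels": stack.config.n_channels,
        "analysis_channels": stack.config.analysis_channels,
        "irf": _irf_to_dict(stack.irf),
        "provenance": stack.provenance,
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        pages = np.ascontiguousarray(np.moveaxis(stack.counts, 2, 0).astype(np.uint32))
        tifffile.imwrite(path, pages, description=json.dumps(meta))
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=stack.counts, compression="gzip")
            f.attrs["channel_width"] = stack.config.channel_width
            f.attrs["n_channels"] = stack.config.n_channels
            f.attrs["analysis_channels"] = stack.config.analysis_channels
            f.attrs["irf"] = json.dumps(_irf_to_dict(stack.irf))
            f.attrs["provenance"] = json.dumps(stack.provenance)
            if stack.truth is not None:
                g = f.create_group("truth")
                for key, m in stack.truth.items():
                    g.create_dataset(key, data=np.asarray(m))
    else:
        raise FormatError(f"unsupported stack container {path.suffix!r}")


def read_flim_stack(path: str | Path) -> FLIMStack:
    """Read a FLIM stack written by :func:`write_flim_stack`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            desc = tf.pages[0].description
            if not desc:
                raise FormatError("TIFF stack missing metadata key 'channel_width' "
                                  "(no JSON image description)")
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError as exc:
                raise FormatError(f"TIFF description is not valid JSON: {exc}") from exc
            pages = tf.asarray()
        for key in _REQUIRED_META:
            if key not in meta:
                raise FormatError(f"stack metadata missing required key {key!r}")
        counts = np.moveaxis(pages, 0, 2).astype(np.int64)
        config = TCSPCConfig(
            channel_width=float(meta["channel_width"]),
            n_channels=int(meta["n_channels"]),
            analysis_channels=int(meta["analysis_channels"]),
        )
        return FLIMStack(
            counts=counts,
            config=config,
            irf=_irf_from_dict(meta["irf"]),
            truth=None,
            provenance=meta.get("provenance", {}),
        )
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for key in ("channel_width", "n_channels", "analysis_channels", "irf"):
                if key not in f.attrs:
                    raise FormatError(f"stack metadata missing required key {key!r}")
            config = TCSPCConfig(
                channel_width=float(f.attrs["channel_width"]),
                n_channels=int(f.attrs["n_channels"]),
                analysis_channels=int(f.attrs["analysis_channels"]),
            )
            irf = _irf_from_dict(json.loads(f.attrs["irf"]))
            provenance = json.loads(f.attrs.get("provenance", "{}"))
            counts = f["counts"][...].astype(np.int64)
            truth = None
            if "truth" in f:
                truth = {k: f["truth"][k][...] for k in f["truth"]}
        return FLIMStack(counts=counts, config=config, irf=irf, truth=truth, provenance=provenance)
    raise FormatError(f"unsupported stack container {path.suffix!r}")


# ---------------------------------------------------------------------------
# delimited text


def write_decay_table(decay: np.ndarray, config: TCSPCConfig, path: str | Path) -> None:
    """Write a decay histogram as CSV with columns channel,time_ns,counts."""
    df = pd.DataFrame(
        {
            "channel": np.arange(config.n_channels),
            "time_ns": config.channel_midpoints(),
            "counts": np.asarray(decay),
        }
    )
    df.to_csv(path, index=False)


def read_decay_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a decay histogram CSV; returns (times_ns, counts).

    Validation failures report the 1-based file line (header is line 1).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse decay table {path}: {exc}") from exc
    for col in ("channel", "time_ns", "counts"):
        if col not in df.columns:
            raise FormatError(f"decay table missing required column {col!r}")
    counts = df["counts"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(counts) | (counts < 0))
    if bad.size:
        raise FormatError(
            f"decay table line {bad[0] + 2}: counts must be finite and non-negative"
        )
    return df["time_ns"].to_numpy(dtype=float), counts


def write_binding_table(series_list, path: str | Path) -> None:
    """Write one or more binding series as CSV
    (concentration_uM,response,condition)."""
    if isinstance(series_list, BindingSeries):
        series_list = [series_list]
    frames = [
        pd.DataFrame(
            {
                "concentration_uM": s.concentrations,
                "response": s.responses,
                "condition": s.condition_label,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_binding_table(path: str | Path) -> list[BindingSeries]:
    """Read binding series CSV, one series per distinct condition label."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse binding table {path}: {exc}") from exc
    for col in ("concentration_uM", "response"):
        if col not in df.columns:
            raise FormatError(f"binding table missing required column {col!r}")
    if "condition" not in df.columns:
        df["condition"] = ""
    conc = df["concentration_uM"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(conc) | (conc < 0))
    if bad.size:
        raise FormatError(
            f"binding table line {bad[0] + 2}: concentration must be finite and >= 0"
        )
    out = []
    for label, sub in df.groupby("condition", sort=False, dropna=False):
        out.append(
            BindingSeries(
                concentrations=sub["concentration_uM"].to_numpy(dtype=float),
                responses=sub["response"].to_numpy(dtype=float),
                condition_label="" if pd.isna(label) else str(label),
            )
        )
    return out


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of one analysis run; round-trips through YAML.

    Every pipeline run writes its resolved configuration beside its
    outputs so that any numerical result is reproducible from the archived
    config + seed alone.
    """

    tcspc: TCSPCConfig = dataclasses.field(default_factory=TCSPCConfig)
    irf: IRFSpec = dataclasses.field(default_factory=IRFSpec)
    tau_D: float = 2.65
    tau_F: float = 0.83
    photon_threshold: int = 150
    binning: str = "2x2-sliding"  # or "2x2-block" or "none"
    f_d_estimator: str = "linear"
    forster_radius: float = 57.0
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tcspc"] = dataclasses.asdict(self.tcspc)
        d["irf"] = _irf_to_dict(self.irf)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["tcspc"] = TCSPCConfig(**d.get("tcspc", {}))
        d["irf"] = _irf_from_dict(d.get("irf", {"kind": "gaussian", "center": 0.5, "fwhm": 0.1}))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise FormatError(f"run config {path} is not a mapping")
        try:
            return cls.from_dict(d)
        except TypeError as exc:
            raise FormatError(f"run config {path}: {exc}") from exc
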