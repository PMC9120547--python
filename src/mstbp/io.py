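"""Record and segment readers/writers plus plain-text run configuration.

Two record dialects are supported:

* CSV — columns ``t, ecg, ppg, abp`` with a header row; the sampling rate is
  inferred from the ``t`` column spacing.
* HDF5 — datasets ``/ecg``, ``/ppg``, ``/abp`` with root attributes ``fs``
  and ``subject_id``.

Segment datasets are HDF5 with ``/x`` (n, 2, 1000), ``/y`` (n, 3), and
``/meta`` (subject id + start index per segment).

The channel order inside ``x`` is fixed as (ECG, PPG). Note that the public
cuff-less BP extract of the MIMIC-II waveforms orders its channels
(PPG, ABP, ECG); :func:`uci_adapter_stub` performs that mapping for a
user-supplied local copy and is never exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import MstNetConfig, TrainConfig
from .preprocess import BPLabels, Segment
from .records import Record

__all__ = [
    "read_record",
    "write_record",
    "write_segments",
    "read_segments",
    "RunConfig",
    "uci_adapter_stub",
]


class FormatError(ValueError):
    """A record or config file does not match the documented layout."""


def write_record(record: Record, path: str | Path) -> None:
    """Write a record as CSV (.csv) or HDF5 (any other suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        t = np.arange(len(record)) / record.fs
        pd.DataFrame(
            {"t": t, "ecg": record.ecg, "ppg": record.ppg, "abp": record.abp}
        ).to_csv(path, index=False)
    else:
        with h5py.File(path, "w") as fh:
            for name in ("ecg", "ppg", "abp"):
                fh.create_dataset(name, data=getattr(record, name))
            fh.attrs["fs"] = record.fs
            fh.attrs["subject_id"] = record.subject_id


def read_record(path: str | Path) -> Record:
    """Read a record written by :func:`write_record` (CSV or HDF5)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        missing = {"t", "ecg", "ppg", "abp"} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        t = df["t"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0 or np.any(dt <= 0):
            raise FormatError(f"{path}: time column must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise FormatError(f"{path}: non-uniform sampling in time column")
        fs = 1.0 / dt[0]
        return Record(
            df["ecg"].to_numpy(float),
            df["ppg"].to_numpy(float),
            df["abp"].to_numpy(float),
            fs=fs,
            subject_id=path.stem,
        )
    with h5py.File(path, "r") as fh:
        missing = {"ecg", "ppg", "abp"} - set(fh.keys())
        if missing:
            raise FormatError(f"{path}: missing datasets {sorted(missing)}")
        arrays = {name: fh[name][...] for name in ("ecg", "ppg", "abp")}
        fs = float(fh.attrs.get("fs", 125.0))
        subject = str(fh.attrs.get("subject_id", path.stem))
    lengths = {len(a) for a in arrays.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: unequal channel lengths {sorted(lengths)}")
    return Record(arrays["ecg"], arrays["ppg"], arrays["abp"], fs=fs, subject_id=subject)


def write_segments(segments: list[Segment], path: str | Path) -> None:
    if not segments:
        raise ValueError("no segments to write")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("x", data=np.stack([s.x for s in segments]))
        fh.create_dataset("y", data=np.stack([s.labels.as_array() for s in segments]))
        meta = np.array(
            [(s.subject_id, s.start_index) for s in segments],
            dtype=[("subject_id", "S64"), ("start_index", "i8")],
        )
        fh.create_dataset("meta", data=meta)


def read_segments(path: str | Path) -> list[Segment]:
    with h5py.File(path, "r") as fh:
        x = fh["x"][...]
        y = fh["y"][...]
        meta = fh["meta"][...]
    return [
        Segment(
            x=x[i],
            labels=BPLabels(sbp=y[i, 0], dbp=y[i, 1], map=y[i, 2]),
            subject_id=meta["subject_id"][i].decode(),
            start_index=int(meta["start_index"][i]),
        )
        for i in range(len(x))
    ]


@dataclass
class RunConfig:
    """Serializable bundle of everything one run needs."""

    in_path: str = ""
    out_path: str = ""
    seed: int = 0
    min_duration_s: float = 0.0
    segment_s: float = 8.0
    denoise: bool = True
    model: MstNetConfig = field(default_factory=MstNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def serialize(self, path: str | Path) -> None:
        """Write a flat ``section.key: value`` plain-text file."""
        lines = []
        for key in ("in_path", "out_path", "seed", "min_duration_s", "segment_s", "denoise"):
            lines.append(f"run.{key}: {getattr(self, key)!r}")
        for section, obj in (("model", self.model), ("train", self.train)):
            for key, value in asdict(obj).items():
                lines.append(f"{section}.{key}: {value!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def parse(cls, path: str | Path) -> "RunConfig":
        import ast

        sections: dict[str, dict] = {"run": {}, "model": {}, "train": {}}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                key, value = line.split(":", 1)
                section, name = key.strip().split(".", 1)
                sections[section][name] = ast.literal_eval(value.strip())
            except (ValueError, KeyError, SyntaxError) as exc:
                raise FormatError(f"{path}:{lineno}: cannot parse {line!r}") from exc
        model_kwargs = sections["model"]
        for key in ("stream_kernels", "module_filters"):
            if key in model_kwargs:
                model_kwargs[key] = tuple(model_kwargs[key])
        return cls(
            model=MstNetConfig(**model_kwargs),
            train=TrainConfig(**sections["train"]),
            **sections["run"],
        )


def uci_adapter_stub(path: str | Path) -> list[Record]:
    """Map a local copy of the public cuff-less BP extract into records.

    The extract stores each record as a (3, n) or (n, 3) array in channel
    order (PPG, ABP, ECG) at 125 Hz; this adapter reorders the channels. The
    external dataset is optional and is never bundled or downloaded; tests do
    not exercise real data through this path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: external data not bundled — supply a local copy of the "
            "UCI cuff-less blood-pressure extract"
        )
    records = []
    with h5py.File(path, "r") as fh:
        for name, dset in fh.items():
            arr = np.asarray(dset[...], dtype=float)
            if arr.ndim != 2:
                raise FormatError(f"{path}/{name}: expected a 2-D channel array")
            if arr.shape[0] != 3:
                arr = arr.T
            if arr.shape[0] != 3:
                raise FormatError(f"{path}/{name}: expected 3 channels")
            ppg, abp, ecg = arr
            # sanity check the declared channel order: ABP is on the mmHg
            # scale while PPG/ECG are unit-scale
            if not (20.0 <= np.median(abp) <= 300.0):
                raise FormatError(
                    f"{path}/{name}: middle channel not on the mmHg scale — "
                    "channel order must be (PPG, ABP, ECG)"
                )
            records.append(Record(ecg, ppg, abp, fs=125.0, subject_id=name))
    return records
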