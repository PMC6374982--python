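"""On-disk containers: ERP sessions (array + JSON sidecar), cohorts, posteriors.

A session is stored as ``<subject>_<session>.npy`` holding the stacked
(n_conditions, channels, time) array, with a ``.json`` sidecar carrying the
montage, sampling rate, peristimulus window, condition order, dose code and
trial counts.  Posteriors are stored as a mean CSV, a covariance ``.npy``
and a free-energy JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .conditions import CONDITIONS
from .forward import SensorErp
from .simulate import ErpDataset
from .vl import GaussianDensity, InversionResult


def session_stem(dataset: ErpDataset) -> str:
    return f"{dataset.subject_id}_{dataset.session}"


def save_session(dataset: ErpDataset, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = session_stem(dataset)
    np.save(out_dir / f"{stem}.npy", dataset.stack())
    ref = dataset.erps[CONDITIONS[0]]
    sidecar = {
        "subject_id": dataset.subject_id,
        "session": dataset.session,
        "dose_code": dataset.dose_code,
        "conditions": list(CONDITIONS),
        "channels": list(ref.channels),
        "sfreq_hz": ref.sfreq,
        "window_ms": list(ref.window_ms),
        "reference": ref.reference,
        "trial_counts": dataset.trial_counts,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir / f"{stem}.npy"


def load_session(npy_path: str | Path) -> ErpDataset:
    npy_path = Path(npy_path)
    meta = json.loads(npy_path.with_suffix(".json").read_text())
    data = np.load(npy_path)
    erps = {
        c: SensorErp(
            data=data[j],
            sfreq=float(meta["sfreq_hz"]),
            window_ms=tuple(meta["window_ms"]),
            channels=tuple(meta["channels"]),
            reference=meta.get("reference", "average"),
        )
        for j, c in enumerate(meta["conditions"])
    }
    return ErpDataset(
        subject_id=meta["subject_id"],
        session=meta["session"],
        dose_code=int(meta["dose_code"]),
        erps=erps,
        trial_counts={k: int(v) for k, v in meta["trial_counts"].items()},
    )


def load_sessions(directory: str | Path) -> list[ErpDataset]:
    files = sorted(Path(directory).glob("*.npy"))
    if not files:
        raise FileNotFoundError(f"no session containers in {directory}")
    return [load_session(f) for f in files]


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_frame().to_csv(path, index=False)


def load_cohort(path: str | Path) -> Cohort:
    return Cohort.from_frame(pd.read_csv(path))


def save_posterior(result: InversionResult, out_dir: str | Path, stem: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    post = result.posterior
    pd.DataFrame({"parameter": post.names, "mean": post.mean}).to_csv(
        out_dir / f"{stem}_mean.csv", index=False
    )
    np.save(out_dir / f"{stem}_cov.npy", post.cov)
    (out_dir / f"{stem}_evidence.json").write_text(
        json.dumps(
            {
                "free_energy": result.free_energy,
                "lambda_post": result.lambda_post,
                "trajectory": list(map(float, result.trajectory)),
            },
            indent=2,
        )
    )


def load_posterior(out_dir: str | Path, stem: str) -> tuple[GaussianDensity, float]:
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / f"{stem}_mean.csv")
    cov = np.load(out_dir / f"{stem}_cov.npy")
    meta = json.loads((out_dir / f"{stem}_evidence.json").read_text())
    dens = GaussianDensity(df["mean"].to_numpy(), cov, tuple(df["parameter"]))
    return dens, float(meta["free_energy"])
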