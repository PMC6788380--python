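"""Session data model, HDF5 archive format and plain-text ingestion.

Archive layout (one file per session)::

    /counts                units x bins int spike counts
    /kinematics/values     bins x coords float marker positions (NaN = missing)
    /kinematics/columns    column names
    /trials                table: start, stop, event times, task, speed,
                           has_kinematics
    /ground_truth/...      optional: true latents and generative parameters

Every archive carries a schema version, the seeds used, and a provenance
string (synthetic config hash or an external-source note).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import preprocess as pp
from .plds import PLDSParams
from .preprocess import GaitEvents, SpikeCountMatrix, Trial

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class SessionManifest:
    """Per-session bookkeeping: unit count, per-task trial tallies,
    kinematics availability, provenance and seeds."""

    session_id: str
    n_units: int
    trial_counts: dict[str, int]
    kinematic_trial_counts: dict[str, int]
    provenance: str = ""
    seeds: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for task, n in self.kinematic_trial_counts.items():
            if n > self.trial_counts.get(task, 0):
                raise ValueError(
                    f"task {task}: kinematics-available count exceeds trial count"
                )


@dataclass
class Session:
    """In-memory session: aligned counts, marker kinematics and trials."""

    counts: SpikeCountMatrix
    kinematics: pd.DataFrame
    trials: list[Trial]
    manifest: SessionManifest
    latents_true: np.ndarray | None = None
    params_true: PLDSParams | None = None

    def validate(self) -> None:
        if len(self.kinematics) != self.counts.n_bins:
            raise ValueError("kinematic frames and spike bins misaligned")
        for tr in self.trials:
            if tr.stop > self.counts.n_bins:
                raise ValueError("trial extends past the recorded bins")
        self.manifest.validate()


def make_manifest(
    counts: SpikeCountMatrix,
    trials: list[Trial],
    session_id: str = "session",
    provenance: str = "",
    seeds: dict | None = None,
) -> SessionManifest:
    tc: dict[str, int] = {}
    kc: dict[str, int] = {}
    for tr in trials:
        tc[tr.task] = tc.get(tr.task, 0) + 1
        if tr.has_kinematics:
            kc[tr.task] = kc.get(tr.task, 0) + 1
    return SessionManifest(
        session_id=session_id,
        n_units=counts.n_units,
        trial_counts=tc,
        kinematic_trial_counts=kc,
        provenance=provenance,
        seeds=dict(seeds or {}),
    )


def as_session(synthetic, session_id: str = "synthetic") -> Session:
    """Wrap a generated synthetic session in the generic container."""
    from .synthetic import config_to_dict

    cfg_hash = hashlib.sha256(
        json.dumps(config_to_dict(synthetic.config), sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = make_manifest(
        synthetic.counts,
        synthetic.trials,
        session_id=session_id,
        provenance=f"synthetic:{cfg_hash}",
        seeds={"generator": synthetic.config.seed},
    )
    return Session(
        counts=synthetic.counts,
        kinematics=synthetic.kinematics,
        trials=synthetic.trials,
        manifest=manifest,
        latents_true=synthetic.latents_true,
        params_true=synthetic.params_true,
    )


def save_session(session: Session, path: str | Path) -> None:
    session.validate()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["session_id"] = session.manifest.session_id
        f.attrs["provenance"] = session.manifest.provenance
        f.attrs["seeds"] = json.dumps(session.manifest.seeds)
        f.create_dataset("counts", data=session.counts.counts)
        f["counts"].attrs["t0"] = session.counts.t0
        g = f.create_group("kinematics")
        g.create_dataset("values", data=session.kinematics.to_numpy(float))
        g.create_dataset(
            "columns",
            data=np.array([c.encode() for c in session.kinematics.columns]),
        )
        tr = f.create_group("trials")
        tr.create_dataset("start", data=[t.start for t in session.trials])
        tr.create_dataset("stop", data=[t.stop for t in session.trials])
        tr.create_dataset("foot_strike_t", data=[t.events.foot_strike_t for t in session.trials])
        tr.create_dataset("toe_off_t", data=[t.events.toe_off_t for t in session.trials])
        tr.create_dataset(
            "next_foot_strike_t", data=[t.events.next_foot_strike_t for t in session.trials]
        )
        tr.create_dataset(
            "task", data=np.array([t.task.encode() for t in session.trials])
        )
        tr.create_dataset(
            "speed",
            data=[np.nan if t.speed is None else t.speed for t in session.trials],
        )
        tr.create_dataset(
            "has_kinematics", data=[t.has_kinematics for t in session.trials]
        )
        if session.latents_true is not None:
            gt = f.create_group("ground_truth")
            gt.create_dataset("latents", data=session.latents_true)
            if session.params_true is not None:
                for name in ("A", "Q", "C", "d", "x0", "Q0"):
                    gt.create_dataset(name, data=getattr(session.params_true, name))


def load_session(path: str | Path) -> Session:
    """Load and validate an archive; recomputed manifest counts must match."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {version}")
        counts = SpikeCountMatrix(f["counts"][()], t0=float(f["counts"].attrs["t0"]))
        cols = [c.decode() for c in f["kinematics/columns"][()]]
        kin = pd.DataFrame(f["kinematics/values"][()], columns=cols)
        tg = f["trials"]
        trials = []
        for i in range(len(tg["start"])):
            speed = float(tg["speed"][i])
            trials.append(
                Trial(
                    int(tg["start"][i]),
                    int(tg["stop"][i]),
                    GaitEvents(
                        float(tg["foot_strike_t"][i]),
                        float(tg["toe_off_t"][i]),
                        float(tg["next_foot_strike_t"][i]),
                    ),
                    tg["task"][i].decode(),
                    speed=None if np.isnan(speed) else speed,
                    has_kinematics=bool(tg["has_kinematics"][i]),
                )
            )
        latents = None
        params = None
        if "ground_truth" in f:
            gt = f["ground_truth"]
            latents = gt["latents"][()]
            if "A" in gt:
                params = PLDSParams(
                    A=gt["A"][()], Q=gt["Q"][()], C=gt["C"][()],
                    d=gt["d"][()], x0=gt["x0"][()], Q0=gt["Q0"][()],
                )
        manifest = make_manifest(
            counts,
            trials,
            session_id=str(f.attrs["session_id"]),
            provenance=str(f.attrs["provenance"]),
            seeds=json.loads(str(f.attrs["seeds"])),
        )
    session = Session(
        counts=counts, kinematics=kin, trials=trials, manifest=manifest,
        latents_true=latents, params_true=params,
    )
    session.validate()
    return session


def save_plds_params(params: PLDSParams, path: str | Path, diagnostics=None) -> None:
    """Serialize fitted model parameters under ``/plds`` with a version tag;
    fit diagnostics go to a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "a") as f:
        if "plds" in f:
            del f["plds"]
        g = f.create_group("plds")
        g.attrs["version"] = 1
        for name in ("A", "Q", "C", "d", "x0", "Q0"):
            g.create_dataset(name, data=getattr(params, name))
    if diagnostics is not None:
        sidecar = path.with_suffix(path.suffix + ".fit.json")
        sidecar.write_text(
            json.dumps(
                {
                    "loglik_trace": list(map(float, diagnostics.loglik_trace)),
                    "n_iter": diagnostics.n_iter,
                    "converged": diagnostics.converged,
                    "messages": diagnostics.messages,
                },
                indent=2,
            )
        )


def load_plds_params(path: str | Path) -> PLDSParams:
    with h5py.File(path, "r") as f:
        if "plds" not in f:
            raise KeyError("archive has no fitted model parameters")
        g = f["plds"]
        if int(g.attrs.get("version", -1)) != 1:
            raise ValueError("unsupported parameter schema version")
        return PLDSParams(
            A=g["A"][()], Q=g["Q"][()], C=g["C"][()], d=g["d"][()],
            x0=g["x0"][()], Q0=g["Q0"][()],
        )


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute simulate -> decode -> report end to end from one config dict.

    ``config`` keys: ``simulate`` (GroundTruthConfig fields), ``decoders``
    (subset of fp/plds/pca/pss), ``dims``, ``folds``. Every artifact in
    ``out_dir`` is stamped with the config hash and seed; rerunning with the
    same config and seed reproduces the archive bit for bit.
    """
    from . import wiener
    from .synthetic import config_from_dict, generate_session

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    gen_cfg = config_from_dict(config.get("simulate", {}))
    gen_cfg.seed = seed
    session = as_session(generate_session(gen_cfg))
    save_session(session, out_dir / "session.h5")

    decoders = config.get("decoders", ["fp", "plds"])
    dims = int(config.get("dims", 12))
    folds = int(config.get("folds", 10))
    summary: dict = {"seed": seed, "config_hash": cfg_hash, "mean_r2": {}}
    targets = wiener.build_targets(session)
    for dec in decoders:
        try:
            spec = wiener.DecoderSpec(
                method=dec, dims=None if dec == "fp" else dims
            )
            results = wiener.run_cv(
                session, spec, folds=folds, seed=seed, targets=targets
            )
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"decode stage failed for decoder {dec!r}") from exc
        mean = wiener.session_mean_r2(results)
        mean.to_csv(out_dir / f"mean_r2_{dec}.csv", header=["r_squared"])
        summary["mean_r2"][dec] = float(mean.mean())
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline complete (config %s, seed %d)", cfg_hash, seed)
    return summary


# ---------------------------------------------------------------------------
# plain-text ingestion
# ---------------------------------------------------------------------------


def load_text_session(
    spike_dir: str | Path,
    markers_csv: str | Path,
    events_csv: str | Path,
    session_id: str = "external",
) -> Session:
    """Assemble a session from delimited text files.

    ``spike_dir`` holds one ``unit*.txt`` file per unit (spike times in
    seconds, one per line); ``markers_csv`` has 100 Hz marker coordinates in
    meters with ``<marker>_x``/``<marker>_y`` columns; ``events_csv`` has one
    row per gait cycle: ``foot_strike_t, toe_off_t, next_foot_strike_t, task,
    speed, has_kinematics``.
    """
    spike_dir = Path(spike_dir)
    unit_files = sorted(spike_dir.glob("unit*.txt"))
    if not unit_files:
        raise FileNotFoundError(f"no unit*.txt files in {spike_dir}")
    markers = pd.read_csv(markers_csv)
    n_bins = len(markers)
    t1 = n_bins * pp.BIN_WIDTH_S
    spikes = [np.loadtxt(uf, ndmin=1) for uf in unit_files]
    counts = pp.bin_spikes(spikes, 0.0, t1)
    if counts.n_bins < n_bins:  # pad trailing silent bins to frame count
        pad = np.zeros((counts.n_units, n_bins - counts.n_bins), dtype=np.int64)
        counts = SpikeCountMatrix(np.hstack([counts.counts, pad]))
    ev = pd.read_csv(events_csv)
    events = [
        GaitEvents(r.foot_strike_t, r.toe_off_t, r.next_foot_strike_t)
        for r in ev.itertuples()
    ]
    trials = pp.segment_trials(
        counts,
        events,
        list(ev["task"]),
        speeds=list(ev["speed"]) if "speed" in ev else None,
        kinematics_ok=list(ev["has_kinematics"]) if "has_kinematics" in ev else None,
    )
    manifest = make_manifest(
        counts, trials, session_id=session_id, provenance=f"text:{spike_dir}"
    )
    session = Session(counts=counts, kinematics=markers, trials=trials, manifest=manifest)
    session.validate()
    return session
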