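"""File formats, run configuration and the simulate -> fit -> dwell -> report
pipeline.

Trace files are self-describing two-column CSV: '#'-prefixed metadata lines
(``# delta_s=``, ``# seed=`` ...), a ``bin,count`` header, then one row per
bin.  Arrival records are one float (seconds) per line with the same comment
convention.  All durations are seconds internally; reports print
milliseconds.  Every output embeds the seed, package version and a config
hash so a run is reconstructible from its output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dwell import (
    DwellPDF,
    DwellSet,
    dwell_pdf,
    extract_dwells,
    fit_exponential,
    pool_dwells,
    relaxation_from_transition,
)
from .gibbs import FitResult, gibbs_fit, sweeps_to_converge
from .model import OFF, ON, Hyperparams, PhotonTrace, ValidationError
from .simulate import ArrivalRecord
from .trace import bimodality_report, count_histogram, model_histogram, qc_flag, rebin

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- trace files

def write_trace(path, trace: PhotonTrace, seed: int | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# delta_s={float(trace.delta)!r}\n")
        if trace.molecule_id:
            fh.write(f"# molecule_id={trace.molecule_id}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("bin,count\n")
        for i, c in enumerate(np.asarray(trace.counts)):
            fh.write(f"{i},{int(c)}\n")


def _parse_metadata(lines):
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, val = body.split("=", 1)
            meta[key.strip()] = val.strip()
    return meta


def read_trace(path, format: str = "counts_csv", delta: float | None = None) -> PhotonTrace:
    """Read a photon-count trace (or bin an arrival list) from disk.

    ``delta`` from the argument wins over a ``# delta_s=`` header (logged);
    for ``arrivals_txt`` input the times are binned at ``delta``.
    """
    path = Path(path)
    if format == "arrivals_txt":
        if delta is None:
            raise ValidationError("delta is required to bin an arrival-time file")
        rec = read_arrivals(path, delta=delta)
        return rebin(rec, delta)
    if format != "counts_csv":
        raise ValidationError("format must be 'counts_csv' or 'arrivals_txt'")

    counts = []
    meta = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta.update(_parse_metadata([line]))
                continue
            if line.lower().startswith("bin"):
                continue
            parts = line.split(",")
            try:
                value = int(parts[-1])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: cannot parse count from {line!r}"
                ) from exc
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {value}")
            counts.append(value)

    file_delta = float(meta["delta_s"]) if "delta_s" in meta else None
    if delta is not None and file_delta is not None and abs(delta - file_delta) > 1e-15:
        logger.info(
            "delta flag %g overrides file header %g for %s", delta, file_delta, path
        )
    use_delta = delta if delta is not None else file_delta
    if use_delta is None:
        raise ValidationError(f"{path}: no delta in header and none supplied")
    return PhotonTrace(
        counts=np.asarray(counts, dtype=np.int64),
        delta=use_delta,
        molecule_id=meta.get("molecule_id", path.stem),
    )


def write_arrivals(path, rec: ArrivalRecord, seed: int | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# resolution_s={float(rec.resolution)!r}\n")
        fh.write(f"# duration_s={float(rec.duration)!r}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for t in rec.times:
            fh.write(f"{float(t)!r}\n")


def read_arrivals(path, delta: float | None = None) -> ArrivalRecord:
    """Read an arrival-time list.

    Without a ``# duration_s`` header the record length is inferred from the
    last photon; if ``delta`` is given the length is rounded up to a whole
    number of bins so that photon is not dropped on binning.
    """
    path = Path(path)
    times = []
    meta = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta.update(_parse_metadata([line]))
                continue
            try:
                times.append(float(line))
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: cannot parse arrival time {line!r}"
                ) from exc
    times = np.asarray(times, dtype=float)
    resolution = float(meta.get("resolution_s", 0.0))
    if "duration_s" in meta:
        duration = float(meta["duration_s"])
    elif delta is not None:
        duration = float(np.ceil((times.max() + 1e-12) / delta)) * delta
    else:
        duration = float(times.max()) + (resolution if resolution > 0 else 1e-12)
    return ArrivalRecord(times=times, resolution=resolution, duration=duration)


def write_dwells(path, D: DwellSet) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# state={D.state_name}\n")
        fh.write(f"# delta_s={float(D.delta)!r}\n")
        fh.write(f"# boundary_policy={D.boundary_policy}\n")
        fh.write(f"# n_events={D.n_events}\n")
        for t in D.durations:
            fh.write(f"{float(t)!r}\n")


def write_dwell_pdf(path, pdf: DwellPDF) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("tau_s,count,density\n")
        for tau, n, p in zip(pdf.grid, pdf.counts, pdf.density):
            fh.write(f"{float(tau)!r},{int(n)},{float(p)!r}\n")


def write_objective_csv(path, fit: FitResult) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sweep,L,emission,initial,transition\n")
        for i, row in enumerate(fit.objective):
            fh.write(f"{i},{float(row[0])!r},{float(row[1])!r},{float(row[2])!r},{float(row[3])!r}\n")


def write_histogram_csv(path, hist, mh=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("n,h,h_model\n")
        model = mh.h_model if mh is not None else [float("nan")] * len(hist.support)
        for n, h, hm in zip(hist.support, hist.h, model):
            fh.write(f"{int(n)},{int(h)},{float(hm)!r}\n")


def summary_to_dict(summary) -> dict:
    return {
        "molecule_id": summary.molecule_id,
        "delta_s": summary.delta,
        "burn_in": summary.burn_in,
        "mu_std": summary.mu_bar.tolist(),
        "lambda_std": summary.lam_bar.tolist(),
        "A_bar": summary.A_bar.tolist(),
        "pi_bar": summary.pi_bar.tolist(),
        "mu_counts": summary.mu_counts.tolist(),
        "var_counts": summary.var_counts.tolist(),
        "w": summary.w.tolist(),
        "n_on_mean": summary.n_on_mean,
        "n_off_mean": summary.n_off_mean,
        "mean_objective": summary.mean_objective,
    }


def save_fit_chains_hdf5(path, fit: FitResult) -> None:
    """Optionally persist the full Gibbs chains (requires h5py)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["version"] = __version__
        h5.attrs["delta_s"] = fit.delta
        h5.attrs["mean"] = fit.mean
        h5.attrs["sd"] = fit.sd
        for name in ("mu_chain", "lam_chain", "A_chain", "pi_chain",
                     "labels_chain", "objective"):
            h5.create_dataset(name, data=getattr(fit, name), compression="gzip")


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    inputs: list = field(default_factory=list)
    delta: float | None = None
    n_iter: int = 1000
    warm_sweeps: int = 10
    burn_in: int = 100
    seed: int = 0
    outdir: str = "blinkhmm_out"
    boundary_policy: str = "include"
    dtau: float = 1e-3
    nu: float = 1.0
    m: float = 0.0
    a: float = 1.0
    b: float = 1.0

    def hyperparams(self) -> Hyperparams:
        return Hyperparams(
            nu=self.nu, m=self.m, a=self.a, b=self.b,
            warm_sweeps=self.warm_sweeps, n_iter=self.n_iter,
            burn_in=self.burn_in,
        )

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Fit every input trace, extract and pool dwells, and write the report.

    Outputs per molecule: fit-summary JSON, objective-trace CSV, histogram
    CSV (with the two-Gaussian model), dwell files; pooled ON/OFF dwell files
    and densities; and ``report.json`` with exponential decay constants,
    transition-matrix relaxation times (across-molecule mean +/- sd) and QC
    flags.  All randomness derives from ``config.seed``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in config.inputs:
        if not Path(p).exists():
            raise ValidationError(f"input path does not exist: {p}")

    provenance = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": config.digest(),
    }
    hp = config.hyperparams()
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.inputs))

    molecules = []
    on_sets, off_sets = [], []
    tau_on_list, tau_off_list = [], []
    for path, child in zip(config.inputs, seeds):
        trace = read_trace(path, delta=config.delta)
        stage = "fit"
        try:
            fit = gibbs_fit(trace, hp, rng=np.random.default_rng(child))
            summary = fit.summary
            stage = "histogram"
            hist = count_histogram(trace)
            mh = model_histogram(summary, hist)
            classification, d_score = bimodality_report(mh)
            flagged, reasons = qc_flag(classification, summary.mean_objective)
            stage = "dwell"
            d_on, d_off = extract_dwells(
                summary.state_marginals, trace.delta, config.boundary_policy
            )
            tau_on, tau_off = relaxation_from_transition(summary.A_bar, trace.delta)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed for molecule "
                f"{trace.molecule_id!r}: {exc}"
            ) from exc
        if d_on.n_events:
            on_sets.append(d_on)
        if d_off.n_events:
            off_sets.append(d_off)
        tau_on_list.append(tau_on)
        tau_off_list.append(tau_off)

        mol_id = trace.molecule_id or Path(path).stem
        record = summary_to_dict(summary)
        record.update(
            classification=classification,
            separation_score=d_score,
            qc_flagged=flagged,
            qc_reasons=reasons,
            tau_on_transition_s=tau_on,
            tau_off_transition_s=tau_off,
            convergence_sweep=sweeps_to_converge(fit.objective_trace),
            **provenance,
        )
        molecules.append(record)
        (outdir / f"{mol_id}.summary.json").write_text(
            json.dumps(record, sort_keys=True, indent=1)
        )
        write_objective_csv(outdir / f"{mol_id}.objective.csv", fit)
        write_histogram_csv(outdir / f"{mol_id}.histogram.csv", hist, mh)
        write_dwells(outdir / f"{mol_id}.dwells_on.txt", d_on)
        write_dwells(outdir / f"{mol_id}.dwells_off.txt", d_off)

    report = dict(provenance)
    report["n_molecules"] = len(molecules)
    report["n_qc_flagged"] = sum(m["qc_flagged"] for m in molecules)
    for name, sets, taus in (
        ("on", on_sets, tau_on_list),
        ("off", off_sets, tau_off_list),
    ):
        if sets:
            pooled = pool_dwells(sets)
            write_dwells(outdir / f"pooled_dwells_{name}.txt", pooled)
            mle = fit_exponential(pooled, "mle")
            lsq = fit_exponential(pooled, "histogram_lsq", dtau=config.dtau)
            write_dwell_pdf(outdir / f"pooled_pdf_{name}.csv",
                            dwell_pdf(pooled, config.dtau))
            report[f"s_{name}_mle_ms"] = mle.s * 1e3
            report[f"s_{name}_mle_stderr_ms"] = mle.stderr * 1e3
            report[f"s_{name}_lsq_ms"] = lsq.s * 1e3
            report[f"n_events_{name}"] = pooled.n_events
        taus = np.asarray(taus)
        report[f"tau_{name}_transition_mean_ms"] = float(taus.mean() * 1e3)
        report[f"tau_{name}_transition_sd_ms"] = float(taus.std(ddof=1) * 1e3) \
            if taus.size > 1 else 0.0
    report["molecules"] = molecules
    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    logger.info("pipeline wrote %d molecule reports to %s", len(molecules), outdir)
    return report
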