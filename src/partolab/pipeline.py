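"""End-to-end orchestration: generate/ingest -> resample -> peaks ->
summaries -> group tests -> GLS -> report.

Every run serializes its config (plus a short hash) into the output
directory and logs each stage; identical seed + config reproduce all
numeric outputs byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .gls import GLSFit, build_design, fit_gls
from .peaks import find_peaks, summaries_to_frame, summarize_animal, window_peaks
from .stats import ContingencyTable2x2, fisher_exact_2x2, kruskal_wallis, mann_whitney
from .synth import write_cohort
from .traces import read_events, read_manifest, read_trace, resample_1hz

__all__ = ["RunArtifacts", "run_pipeline", "make_report"]

log = logging.getLogger("partolab")


@dataclass
class RunArtifacts:
    outdir: Path
    summaries: pd.DataFrame
    stats_report: pd.DataFrame
    gls_fit: GLSFit | None
    peak_tables: dict[str, pd.DataFrame]
    window_traces: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    excluded_animals: list[str] = field(default_factory=list)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return out
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


@_stage("ingest")
def _ingest(config: RunConfig, outdir: Path):
    if config.cohort is not None:
        manifest_path = write_cohort(config.cohort, outdir / "cohort")
    else:
        manifest_path = Path(config.manifest)
    manifest = read_manifest(manifest_path)
    if len(manifest) == 0:
        raise ValueError("manifest lists no animals")
    events = read_events(manifest["events_path"].iloc[0])
    return manifest, events


@_stage("peaks")
def _detect_and_summarize(config: RunConfig, outdir: Path, manifest, events):
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(parents=True, exist_ok=True)
    summaries, peak_tables, window_traces = [], {}, {}
    for row in manifest.itertuples():
        trace = read_trace(row.trace_path, animal_id=row.animal_id, group=row.group)
        trace1 = resample_1hz(trace)
        peaks = find_peaks(trace1, config.min_height, config.min_prominence)
        record = events.get(row.animal_id)
        if record is None:
            raise ValueError(f"no delivery events for animal {row.animal_id}")
        bounds = (float(trace1.timestamps[0]), float(trace1.timestamps[-1]) + 1.0)
        ps = window_peaks(peaks, record, config.window, bounds)
        summaries.append(
            summarize_animal(
                ps, record, d_drg=row.d_drg, d_uterus=row.d_uterus,
                zt_boundary=config.zt_boundary,
            )
        )
        table = pd.DataFrame(
            {
                "time_s": [p.time for p in ps.peaks],
                "height_mmHg": [p.height for p in ps.peaks],
                "prominence_mmHg": [p.prominence for p in ps.peaks],
            }
        )
        table.to_csv(peak_dir / f"{row.animal_id}.csv", index=False, float_format="%.6f")
        peak_tables[row.animal_id] = table
        lo, hi = ps.window_bounds
        sel = (trace1.timestamps >= lo) & (trace1.timestamps < hi)
        window_traces[row.animal_id] = (trace1.timestamps[sel], trace1.pressure[sel])
    frame = summaries_to_frame(summaries)
    frame.to_csv(outdir / "summaries.csv", index=False, float_format="%.6f")
    return frame, peak_tables, window_traces


@_stage("stats")
def _group_stats(config: RunConfig, outdir: Path, summaries: pd.DataFrame) -> pd.DataFrame:
    rows = []
    groups = list(dict.fromkeys(summaries["group"]))  # stable order
    is_control = (summaries["d_drg"] == 0) & (summaries["d_uterus"] == 0)
    control_label = summaries.loc[is_control, "group"].iloc[0] if is_control.any() else None

    def add(test, outcome, stat, p, n_desc):
        rows.append(
            {"test": test, "outcome": outcome, "statistic": stat, "p_value": p, "n": n_desc}
        )

    for outcome in ("mean_peak_pressure", "mean_interpup_interval"):
        samples = [
            summaries.loc[summaries["group"] == g, outcome].dropna().to_numpy()
            for g in groups
        ]
        sizes = "/".join(str(len(s)) for s in samples)
        if len(groups) >= 2 and all(len(s) >= 1 for s in samples):
            kw = kruskal_wallis(samples)
            add("kruskal_wallis", outcome, kw.h, kw.p_value, sizes)
        else:
            add("kruskal_wallis", outcome, np.nan, np.nan, sizes)
        if control_label is not None:
            ctrl = summaries.loc[summaries["group"] == control_label, outcome].dropna()
            for g in groups:
                if g == control_label:
                    continue
                other = summaries.loc[summaries["group"] == g, outcome].dropna()
                if len(ctrl) and len(other):
                    mw = mann_whitney(ctrl.to_numpy(), other.to_numpy())
                    add(
                        f"mann_whitney[{control_label} vs {g}]", outcome,
                        mw.u, mw.p_value, f"{len(ctrl)}/{len(other)}",
                    )

    # onset-after-ZT boundary association: control vs pooled knockouts
    if control_label is not None and (~is_control).any():
        after = summaries["onset_after_zt3"].astype("boolean")
        a = int(((is_control) & ~after.fillna(False)).sum())
        b = int(((is_control) & after.fillna(False)).sum())
        c = int(((~is_control) & ~after.fillna(False)).sum())
        d = int(((~is_control) & after.fillna(False)).sum())
        p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        add("fisher_exact[onset_after_zt3]", "onset_after_zt3", np.nan, p, f"{a + b}/{c + d}")

    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "stats_report.csv", index=False, float_format="%.6g")
    return frame


@_stage("gls")
def _gls(config: RunConfig, outdir: Path, summaries: pd.DataFrame):
    usable = summaries.dropna(subset=["mean_peak_pressure"])
    excluded = sorted(set(summaries["animal_id"]) - set(usable["animal_id"]))
    if excluded:
        log.warning("excluding %d animal(s) with no peaks in window: %s", len(excluded), excluded)
    counts = usable.groupby("group").size()
    fit = None
    lines = []
    if usable["group"].nunique() >= 2 and (counts >= 2).all():
        design = build_design(usable)
        fit = fit_gls(
            design,
            tol=config.gls_tol,
            max_iter=config.gls_max_iter,
            one_step=config.gls_one_step,
        )
        lines.append("coef,estimate_mmHg,se,t,p_one_sided,df")
        for name, b, s, t, p in zip(fit.coef_names, fit.beta, fit.se, fit.t_stats, fit.p_one_sided):
            lines.append(f"{name},{b:.6f},{s:.6f},{t:.6f},{p:.6g},{fit.df}")
        lines.append("")
        lines.append("group,sigma2_mmHg2")
        for g, v in sorted(fit.sigma2_by_group.items()):
            lines.append(f"{g},{v:.6f}")
        lines.append("")
        lines.append(f"converged,{fit.converged}")
        lines.append(f"n_iter,{fit.n_iter}")
    else:
        lines.append("gls,not_applicable (need >=2 groups with >=2 animals each)")
    (outdir / "gls_report.csv").write_text("\n".join(lines) + "\n")
    return fit, excluded


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Run the full analysis; returns in-memory artifacts, writes tables,
    config copy, and a run log under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("partolab %s, config hash %s", __version__, config_hash(config))
        config.to_yaml(outdir / "run_config.yaml")
        manifest, events = _ingest(config, outdir)
        summaries, peak_tables, window_traces = _detect_and_summarize(
            config, outdir, manifest, events
        )
        stats_report = _group_stats(config, outdir, summaries)
        fit, excluded = _gls(config, outdir, summaries)
        return RunArtifacts(
            outdir=outdir,
            summaries=summaries,
            stats_report=stats_report,
            gls_fit=fit,
            peak_tables=peak_tables,
            window_traces=window_traces,
            excluded_animals=excluded,
        )
    finally:
        log.removeHandler(handler)
        handler.close()


def make_report(artifacts: RunArtifacts) -> Path:
    """Human-readable summary: per-group table, test results, a detected-peaks
    trace figure and the cohort pressure heatmap over the analysis window."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = artifacts.outdir
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    s = artifacts.summaries
    if len(s) == 0:
        raise StageError("[report] no animals to report on")

    per_group = s.groupby("group", sort=False).agg(
        n=("animal_id", "size"),
        mean_peak_pressure=("mean_peak_pressure", "mean"),
        mean_interpup_interval=("mean_interpup_interval", "mean"),
        n_onset_after=("onset_after_zt3", "sum"),
    )

    # one representative trace per group with detected peaks
    fig, axes = plt.subplots(
        len(per_group), 1, figsize=(8, 2.2 * len(per_group)), squeeze=False, sharex=False
    )
    for ax, (group, sub) in zip(axes.ravel(), s.groupby("group", sort=False)):
        animal = sub["animal_id"].iloc[0]
        t, p = artifacts.window_traces[animal]
        ax.plot(t / 3600.0, p, lw=0.5, color="k")
        tab = artifacts.peak_tables[animal]
        ax.plot(tab["time_s"] / 3600.0, tab["height_mmHg"], "rv", ms=4)
        ax.set_title(f"{group}: {animal}", fontsize=9)
        ax.set_ylabel("mmHg")
    axes.ravel()[-1].set_xlabel("ZT (h)")
    fig.tight_layout()
    fig.savefig(figdir / "traces_with_peaks.png", dpi=120)
    plt.close(fig)

    # pressure heatmap: animals x time over each animal's analysis window
    rows, labels = [], []
    width = max((len(t) for t, _ in artifacts.window_traces.values()), default=0)
    for animal in s["animal_id"]:
        _, p = artifacts.window_traces[animal]
        rows.append(np.pad(p, (0, width - len(p)), constant_values=np.nan))
        labels.append(animal)
    if rows:
        fig, ax = plt.subplots(figsize=(8, 0.25 * len(rows) + 1.5))
        im = ax.imshow(np.vstack(rows), aspect="auto", cmap="magma", interpolation="nearest")
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
        ax.set_xlabel("seconds into window")
        fig.colorbar(im, label="mmHg")
        fig.tight_layout()
        fig.savefig(figdir / "pressure_heatmap.png", dpi=120)
        plt.close(fig)

    lines = ["# partolab run report", ""]
    lines.append("## Per-group summary\n")
    lines.append(per_group.to_string(float_format=lambda v: f"{v:.3f}"))
    lines.append("\n## Group tests\n")
    if len(artifacts.stats_report):
        lines.append(artifacts.stats_report.to_string(index=False))
    else:
        lines.append("not applicable (single animal or single group)")
    lines.append("\n## GLS knockout contrasts\n")
    fit = artifacts.gls_fit
    if fit is None:
        lines.append("not applicable (need >=2 groups with >=2 animals each)")
    else:
        for name, b, se, t, p in zip(fit.coef_names, fit.beta, fit.se, fit.t_stats, fit.p_one_sided):
            lines.append(f"{name}: {b:+.2f} mmHg (se {se:.2f}, t {t:.2f}, one-sided p {p:.4g})")
        lines.append(f"df = {fit.df}, converged = {fit.converged} in {fit.n_iter} iterations")
    if artifacts.excluded_animals:
        lines.append(
            f"\nexcluded from GLS (no peaks in window): {', '.join(artifacts.excluded_animals)}"
        )
    report = outdir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
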