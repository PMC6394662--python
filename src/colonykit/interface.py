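"""Batch orchestration: count plates, fit size distributions, simulate.

The workflow has two halves. ``run_count`` processes a batch of plate
scans with ONE set of resolved parameters — auto values (sigma, rolling
radius, threshold) are resolved on the first image and then frozen, so
every plate of a batch is treated identically — and writes a colony-size
text file plus a diagnostics JSON per plate and a batch summary.
``run_fit`` reads colony-size files, builds histograms, fits the Weibull
and Gaussian models and writes fit JSONs, plots and (for > 1 group) a
comparison table. ``run_simulate`` renders synthetic plates with ground
truth. All three return a process exit status; the click CLI in
:mod:`colonykit.cli` is a thin wrapper over them.

Every run serializes its fully resolved configuration next to the
outputs, so re-running from that file reproduces the results.
"""

from __future__ import annotations

import glob as globlib
import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import plate_io, preprocess, segmentation, sizedist, synthetic
from .errors import ColonyKitError, InsufficientDataError

logger = logging.getLogger("colonykit")


def _expand_inputs(patterns) -> list[Path]:
    if isinstance(patterns, (str, Path)):
        patterns = [patterns]
    paths: list[Path] = []
    for pat in patterns:
        matched = sorted(globlib.glob(str(pat)))
        paths.extend(Path(m) for m in matched)
    # de-duplicate, keep order
    seen, unique = set(), []
    for p in paths:
        if p not in seen:
            seen.add(p)
            unique.append(p)
    return unique


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n",
                    encoding="utf-8")


def run_count(inputs, out_dir, params: preprocess.PipelineParams | None = None,
              dpi: float | None = None, unit: str = "pixel^2") -> int:
    """Count colonies on every image matching ``inputs``; freeze params once.

    Writes per plate: ``<stem>.sizes.txt`` and ``<stem>.diagnostics.json``;
    plus ``batch_summary.json`` and ``resolved_config.json`` for the batch.
    Returns 0 on success, 1 when no input matches or any plate fails
    (remaining plates are still processed).
    """
    paths = _expand_inputs(inputs)
    if not paths:
        logger.error("no input images match %r", inputs)
        return 1
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = params or preprocess.PipelineParams()

    frozen = None   # params after resolving autos on the first image
    summary, failed = [], 0
    for path in paths:
        try:
            plate = plate_io.load_plate_image(path)
            if dpi is not None:
                plate.resolution_dpi = float(dpi)
            if not plate.has_dpi:
                logger.warning("%s: no DPI metadata; using fallback %.0f DPI "
                               "(pass --dpi to override)", path.name,
                               params.fallback_dpi)
            use = frozen if frozen is not None else params
            records, diag = segmentation.process_plate(plate, use)
            if frozen is None:
                r = diag["resolved"]
                frozen = preprocess.PipelineParams(
                    sigma=r["sigma"],
                    rolling_radius=r["rolling_radius"],
                    threshold=r["threshold"],
                    threshold_method=params.threshold_method,
                    roi_margin=params.roi_margin,
                    roi_center=params.roi_center,
                    roi_radius=params.roi_radius,
                    min_area=r["min_area"],
                    max_area=params.max_area,
                    circ_min=params.circ_min,
                    circ_max=params.circ_max,
                    min_peak_distance=params.min_peak_distance,
                    fallback_dpi=params.fallback_dpi,
                )
                _write_json({"resolved_on": path.name, **frozen.to_dict()},
                            out_dir / "resolved_config.json")
            plate_io.write_colony_sizes(
                records, unit=unit, path=out_dir / f"{path.stem}.sizes.txt",
                plate_id=plate.source_id,
                params={"sigma": diag["resolved"]["sigma"],
                        "rolling_radius": diag["resolved"]["rolling_radius"],
                        "threshold": diag["resolved"]["threshold"]},
            )
            diag_out = {k: v for k, v in diag.items() if k not in ("mask", "labels")}
            _write_json(diag_out, out_dir / f"{path.stem}.diagnostics.json")
            summary.append({"plate": path.stem, "count": diag["count"]})
            logger.info("%s: %d colonies", path.name, diag["count"])
        except (ColonyKitError, OSError) as exc:
            logger.error("%s failed: %s", path, exc)
            failed += 1
    _write_json({"plates": summary, "n_failed": failed},
                out_dir / "batch_summary.json")
    return 1 if failed else 0


def run_fit(inputs, out_dir, n_bins="auto", model: str = "both",
            fix_c: float | None = None, make_plots: bool = True) -> int:
    """Fit size distributions for every colony-size file; one group per file.

    Writes ``<stem>.fit.json`` (histogram spec, both fits, derived µ/σ) and
    a plot per group, plus ``comparison.csv`` when there is more than one
    group. Unconverged fits are flagged in the JSON, not treated as errors;
    files too small to fit still get their histogram written.
    """
    paths = _expand_inputs(inputs)
    if not paths:
        logger.error("no input size files match %r", inputs)
        return 1
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    groups, fits = {}, {}
    status = 0
    for path in paths:
        try:
            csf = plate_io.read_colony_sizes(path)
        except ColonyKitError as exc:
            logger.error("%s failed to parse: %s", path, exc)
            return 1
        payload = {"group": csf.plate_id, "n": int(csf.areas.size),
                   "unit": csf.unit}
        try:
            hist = sizedist.build_histogram(csf.areas, n_bins=n_bins)
            payload["histogram"] = {
                "bin_edges": hist.bin_edges.tolist(),
                "counts": hist.counts.tolist(),
                "densities": hist.densities.tolist(),
            }
            wfit = gfit = None
            if model in ("weibull", "both"):
                wfit = sizedist.fit_weibull(hist, fix_c=fix_c)
                payload["weibull"] = asdict(wfit)
            if model in ("gaussian", "both"):
                gfit = sizedist.fit_gaussian(hist)
                payload["gaussian"] = asdict(gfit)
            if wfit is not None:
                groups[csf.plate_id] = csf.areas
                fits[csf.plate_id] = wfit
            if make_plots:
                _plot_fit(hist, wfit, gfit, csf.plate_id,
                          out_dir / f"{path.stem}.fit.png")
        except InsufficientDataError as exc:
            logger.warning("%s: %s (histogram written, no fit)", path.name, exc)
            payload["error"] = str(exc)
        _write_json(payload, out_dir / f"{path.stem}.fit.json")

    if len(groups) > 1:
        comparison = sizedist.compare_groups(groups, n_bins=n_bins, fix_c=fix_c)
        comparison.summary.to_csv(out_dir / "comparison.csv")
        comparison.pairwise.to_csv(out_dir / "pairwise.csv", index=False)
        if make_plots:
            _plot_groups(comparison, out_dir / "groups.png")
    return status


def run_simulate(out_dir, preset: str | None = None,
                 spec: synthetic.SyntheticPlateSpec | None = None,
                 seed: int = 0, n_colonies: int = 50,
                 n_plates: int = 1) -> int:
    """Render synthetic plates (image + ground-truth JSON sidecars)."""
    try:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i in range(n_plates):
            s = seed + i
            if spec is not None:
                plate_spec = synthetic.SyntheticPlateSpec(**{**spec.to_dict(),
                                                             "seed": s})
            elif preset is not None:
                plate_spec = synthetic.category_preset(preset, seed=s,
                                                       n_colonies=n_colonies)
            else:
                plate_spec = synthetic.SyntheticPlateSpec(seed=s,
                                                          n_colonies=n_colonies)
            stem = f"plate_{i:03d}_seed{s}"
            synthetic.save_synthetic_plate(plate_spec, out_dir, stem=stem)
            _write_json(plate_spec.to_dict(), out_dir / f"{stem}.spec.json")
        return 0
    except ColonyKitError as exc:
        logger.error("simulation failed: %s", exc)
        return 1


def _plot_fit(hist, wfit, gfit, title, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist.centers, hist.densities, width=hist.widths, alpha=0.5,
           color="steelblue", label=f"data (n={hist.n_total})")
    xs = np.linspace(hist.bin_edges[0] + 1e-9, hist.bin_edges[-1], 400)
    if wfit is not None:
        ax.plot(xs, sizedist.weibull_density(xs, wfit.a, wfit.b, wfit.c),
                "r-", label=f"Weibull µ={wfit.mu:.1f} σ={wfit.sigma:.1f}")
    if gfit is not None:
        ax.plot(xs, sizedist.gaussian_density(xs, gfit.mu, gfit.sigma,
                                              gfit.amplitude),
                "g--", label=f"Gaussian µ={gfit.mu:.1f} σ={gfit.sigma:.1f}")
    ax.set_xlabel("colony size")
    ax.set_ylabel("density")
    ax.set_title(str(title))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_groups(comparison, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for name, hist in comparison.histograms.items():
        ax1.step(hist.centers, hist.densities, where="mid", label=str(name))
    ax1.set_xlabel("colony size")
    ax1.set_ylabel("density")
    ax1.legend()
    names = list(comparison.summary.index)
    mus = comparison.summary["mu"].to_numpy()
    sigmas = comparison.summary["sigma"].to_numpy()
    ax2.bar(range(len(names)), mus, yerr=sigmas, capsize=4, color="gray")
    ax2.set_xticks(range(len(names)), [str(n) for n in names], rotation=30)
    ax2.set_ylabel("mean colony size (µ ± σ)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
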