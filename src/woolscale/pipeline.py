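"""End-to-end run: measure fibres, fit the perimeter model, estimate dye
diffusion, and validate — with CSV/JSON outputs and QC plots."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import fit_perimeter_model, fit_linear_relation, spi_band_check
from .io import RunConfig, read_image, read_uptake_csv
from .kinetics import DyebathRecord, aggregate_replicates, fit_hill
from .morphometry import measure_fibre

__all__ = ["run_pipeline", "measurements_to_frame"]


def measurements_to_frame(measurements) -> pd.DataFrame:
    rows = [
        {
            "id": m.id,
            "diameter_um": m.diameter_um,
            "diameter_cv_pct": m.diameter_cv_pct,
            "perimeter_per_100um": m.total_perimeter_per_100um,
            "scale_count": m.scales_per_100um,
            "spi": m.spi,
            "pattern": m.pattern.value,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows)


def _windows_frame(measurements) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for w in m.windows:
            rows.append(
                {
                    "id": m.id,
                    "window_index": w.window_index,
                    "start_um": w.start_um,
                    "end_um": w.end_um,
                    "perimeter_um": w.perimeter_um,
                    "full_scales": w.full_scales,
                    "partial_scales": w.partial_scales,
                    "scale_count": w.scale_count,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    image_paths=(),
    uptake_csvs=(),
    baths: dict[str, DyebathRecord] | None = None,
) -> dict:
    """Execute measure -> correlate -> kinetics stages and write the bundle.

    ``uptake_csvs`` maps group labels (e.g. breeds) to CSV paths; ``baths``
    maps the same labels to bath records.  Stages without inputs are skipped
    and noted in the report.  All outputs are deterministic for fixed inputs
    and config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "version": __version__, "stages": {}}

    measurements = []
    if image_paths:
        try:
            for p in image_paths:
                measurements.append(
                    read_image(p) if not hasattr(p, "pixels") else p
                )
            measurements = [
                measure_fibre(img, window_um=config.window_um) for img in measurements
            ]
        except Exception as exc:  # noqa: BLE001 - stage-tagged abort
            raise RuntimeError(f"measure stage failed: {exc}") from exc
        fibre_df = measurements_to_frame(measurements)
        fibre_df.to_csv(out / "fibres.csv", index=False)
        _windows_frame(measurements).to_csv(out / "windows.csv", index=False)
        report["stages"]["measure"] = {"n_fibres": len(measurements)}
    else:
        report["stages"]["measure"] = "skipped: no images"

    model = None
    if len(measurements) >= 3:
        try:
            fibre_df = measurements_to_frame(measurements)
            model = fit_perimeter_model(
                fibre_df["diameter_um"], fibre_df["perimeter_per_100um"]
            )
        except Exception as exc:
            raise RuntimeError(f"correlate stage failed: {exc}") from exc
        (out / "perimeter_model.json").write_text(
            json.dumps(
                {
                    "a": model.a,
                    "b": model.b,
                    "r_squared_centered": model.r_squared,
                    "r_squared_uncentered": model.r_squared_uncentered,
                    "n": model.n,
                },
                indent=2,
            )
        )
        bands = []
        for m in measurements:
            chk = spi_band_check(m.diameter_um, m.spi, config.spi_bands)
            bands.append({"id": m.id, "band": chk.band, "spi_in_range": chk.in_range})
        report["stages"]["correlate"] = {
            "a": model.a,
            "b": model.b,
            "r_squared": model.r_squared,
            "band_checks": bands,
        }
    else:
        report["stages"]["correlate"] = "skipped: fewer than 3 measured fibres"

    kinetics_rows = []
    if uptake_csvs:
        try:
            for label, csv_path in dict(uptake_csvs).items():
                bath = (baths or {})[label]
                series = read_uptake_csv(csv_path, bath)
                fits = [fit_hill(s, cutoff=config.hill_cutoff) for s in series]
                mean_d, stderr = aggregate_replicates(fits)
                kinetics_rows.append(
                    {
                        "group": label,
                        "D_cm2_per_s": mean_d,
                        "stderr_D_cm2_per_s": stderr,
                        "D_display_1e8": round(mean_d * 1e8, 3),
                        "stderr_display_1e8": round(stderr * 1e8, 3),
                        "n_replicates": len(fits),
                    }
                )
        except Exception as exc:
            raise RuntimeError(f"kinetics stage failed: {exc}") from exc
        pd.DataFrame(kinetics_rows).to_csv(out / "kinetics.csv", index=False)
        report["stages"]["kinetics"] = {"groups": [r["group"] for r in kinetics_rows]}
    else:
        report["stages"]["kinetics"] = "skipped: no uptake data"

    if measurements and kinetics_rows and model is not None:
        fibre_df = measurements_to_frame(measurements)
        d_by_group = {r["group"]: r["D_cm2_per_s"] for r in kinetics_rows}
        common = [
            (row["diameter_um"], d_by_group[row["id"]])
            for _, row in fibre_df.iterrows()
            if row["id"] in d_by_group
        ]
        if len(common) >= 2:
            rel = fit_linear_relation(common, predictor="mean_diameter")
            report["stages"]["d_vs_diameter"] = dataclasses.asdict(rel)

    _plots(out, measurements, kinetics_rows)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _plots(out: Path, measurements, kinetics_rows) -> None:
    if not measurements:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = measurements_to_frame(measurements)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].scatter(df["diameter_um"], df["perimeter_per_100um"])
    axes[0].set_xlabel("diameter (um)")
    axes[0].set_ylabel("perimeter per 100 um (um)")
    axes[1].scatter(df["diameter_um"], df["spi"])
    axes[1].set_xlabel("diameter (um)")
    axes[1].set_ylabel("SPI")
    fig.tight_layout()
    fig.savefig(out / "morphometry.png", dpi=120)
    plt.close(fig)

    if kinetics_rows:
        kdf = pd.DataFrame(kinetics_rows)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(
            range(len(kdf)),
            kdf["D_display_1e8"],
            yerr=kdf["stderr_display_1e8"],
            fmt="o",
        )
        ax.set_xticks(range(len(kdf)), kdf["group"])
        ax.set_ylabel("D x 1e-8 (cm^2/s)")
        fig.tight_layout()
        fig.savefig(out / "kinetics.png", dpi=120)
        plt.close(fig)
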