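"""End-to-end pipeline: correct -> segment -> straighten -> fit ->
polarity/dosage metrics -> dose-response tables.

Per-embryo failures are isolated: a failing embryo contributes a flagged
row, and only if more than half the cohort fails does the run abort.
Reruns with identical config and inputs produce byte-identical tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import correction, cortex, io, polarity
from .config import PipelineConfig, RunManifest, checksum_file
from .errors import ConfigError, ParmapError, PipelineError
from .images import read_tiff


def _list_tiffs(directory) -> list[Path]:
    d = Path(directory)
    if not d.is_dir():
        raise ConfigError(f"not a directory: {directory}")
    return sorted(p for p in d.iterdir() if p.suffix.lower() in (".tif", ".tiff"))


def _protein_roles(image, cfg) -> list[str]:
    roles = [r for r in image.channel_roles if r != cfg.af_channel]
    ordered = [r for r in (cfg.signal_channel, cfg.ppar_channel) if r in roles]
    return ordered or roles


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run the full quantitation on a directory of embryo TIFFs.

    Returns the cohort table; writes cohort.csv, per-embryo contours and
    profiles, trend/variance tables, the resolved config and the run
    manifest into ``config.output_dir``.
    """
    config.validate()
    manifest = RunManifest(config_hash=config.content_hash(), started=RunManifest.now())
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    image_paths = _list_tiffs(config.images_dir)
    if not image_paths:
        raise ConfigError(f"no TIFF images found in {config.images_dir}")
    control_paths = _list_tiffs(config.controls_dir) if config.controls_dir else []
    for p in image_paths + control_paths:
        manifest.input_checksums[p.name] = checksum_file(p)

    # --- autofluorescence model from unlabeled controls -------------------
    af_model = None
    if control_paths:
        controls, masks = [], []
        for p in control_paths:
            img = read_tiff(p)
            green = next(r for r in img.channel_roles if r != config.af_channel)
            contour = cortex.segment_embryo(img, channel=config.af_channel, refine=False)
            controls.append((img, green))
            masks.append(contour.mask)
        af_model = correction.fit_af_model(
            [c[0] for c in controls],
            masks,
            mode=config.correction_mode,
            green_role=controls[0][1],
            af_role=config.af_channel,
        )
        manifest.stages["af_model"] = f"ok (m={af_model.slope:.4f})"

    # --- per-embryo quantitation ------------------------------------------
    rows: list[dict] = []
    per_embryo: dict[str, dict] = {}
    n_failed = 0
    for p in image_paths:
        embryo_id = p.stem
        row: dict = {"embryo_id": embryo_id, "flags": ""}
        try:
            img = read_tiff(p)
            roles = _protein_roles(img, config)
            contour = cortex.segment_embryo(
                img,
                channel=roles if len(roles) > 1 else roles[0],
                n_points=config.n_contour_points,
                anterior_marker=(
                    config.anterior_marker if config.anterior_marker in img.channel_roles else None
                ),
            )
            if af_model is not None:
                for role in roles:
                    img = correction.correct_image(
                        img,
                        af_model,
                        mode=config.correction_mode,
                        green_role=role,
                        af_role=config.af_channel,
                        mask=contour.mask,
                    )
            # register the membrane midline on the summed protein channels:
            # their domains tile the perimeter, pinning the centre everywhere
            registration = None
            if len(roles) > 1:
                st_all = cortex.straighten_cortex(
                    img,
                    contour,
                    channel=roles,
                    width_px=config.width_px,
                    smooth_window_px=config.smooth_window_px,
                )
                registration = cortex.fit_membrane_profiles(st_all)
            info = {"contour": contour, "profiles": {}, "means": {}}
            for role in roles:
                st = cortex.straighten_cortex(
                    img,
                    contour,
                    channel=role,
                    width_px=config.width_px,
                    smooth_window_px=config.smooth_window_px,
                )
                prof = cortex.fit_membrane_profiles(st, fixed_center=registration)
                info["profiles"][role] = prof
                info["means"][role] = cortex.whole_embryo_mean(img, contour.mask, role)
                row[f"cortical_anterior_{role}"] = cortex.cortical_mean(
                    prof, "anterior", config.fraction
                )
                row[f"cortical_posterior_{role}"] = cortex.cortical_mean(
                    prof, "posterior", config.fraction
                )
                io.write_profile(out / f"profile_{embryo_id}_{role}.csv", prof)
            io.write_contour(out / f"contour_{embryo_id}.csv", contour)
            if contour.flags:
                row["flags"] = ";".join(contour.flags)
            per_embryo[embryo_id] = info
        except ParmapError as exc:
            n_failed += 1
            row["flags"] = f"failed:{type(exc).__name__}"
        rows.append(row)

    if n_failed > len(image_paths) / 2:
        raise PipelineError(f"{n_failed}/{len(image_paths)} embryos failed")
    manifest.stages["quantify"] = f"ok ({len(image_paths) - n_failed}/{len(image_paths)})"

    # --- dosage normalization and composite asymmetry ---------------------
    control_ids = [Path(name).stem for name in config.dosage_controls]
    have_controls = [e for e in control_ids if e in per_embryo]
    roles_seen = sorted({r for info in per_embryo.values() for r in info["profiles"]})
    control_mean: dict[str, float] = {}
    peaks: dict[str, float] = {}
    for role in roles_seen:
        pool = have_controls if have_controls else list(per_embryo)
        means = [per_embryo[e]["means"][role] for e in pool if role in per_embryo[e]["means"]]
        profs = [per_embryo[e]["profiles"][role] for e in pool if role in per_embryo[e]["profiles"]]
        if means:
            control_mean[role] = float(np.mean(means))
            peaks[role] = polarity.wildtype_peak(profs)

    apar, ppar = config.signal_channel, config.ppar_channel
    for row in rows:
        info = per_embryo.get(row["embryo_id"])
        if info is None:
            continue
        for role, mean in info["means"].items():
            if control_mean.get(role, 0) > 0:
                row[f"dosage_{role}"] = mean / control_mean[role]
        if apar in info["profiles"] and ppar in info["profiles"]:
            try:
                m = polarity.pole_concentrations(
                    info["profiles"][apar],
                    info["profiles"][ppar],
                    peaks[apar],
                    peaks[ppar],
                    fraction=config.fraction,
                )
                row["asi_composite"] = polarity.asi_composite(m)
            except ParmapError:
                row["flags"] = (row["flags"] + ";asi_failed").strip(";")
        if apar in info["profiles"]:
            est = polarity.domain_boundary(info["profiles"][apar], "anterior")
            row["boundary_s"] = est.s_b
        if ppar in info["profiles"]:
            prof = info["profiles"][ppar]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = (prof.amplitude + prof.cytoplasm) / prof.cytoplasm
            ok = np.isfinite(ratio)
            if ok.sum() >= 8:
                call = polarity.detect_domains(
                    ratio[ok],
                    s=prof.s[ok],
                    theta_high=config.theta_high,
                    theta_low=config.theta_low,
                    min_arc=config.min_arc,
                )
                row["domain_call"] = call.category

    cohort = pd.DataFrame(rows)
    io.write_cohort(out / "cohort.csv", cohort)

    # --- dose-response over the cohort ------------------------------------
    from . import doseresponse

    dose_col = f"dosage_{apar}" if f"dosage_{apar}" in cohort.columns else None
    for pheno in config.trend_phenotypes:
        if pheno not in cohort.columns or dose_col is None:
            manifest.warnings.append(f"trend skipped: no column {pheno}")
            continue
        sub = cohort[[dose_col, pheno]].dropna()
        if len(sub) < 10:
            manifest.warnings.append(f"trend skipped: <10 embryos for {pheno}")
            continue
        x, y = sub[dose_col].to_numpy(float), sub[pheno].to_numpy(float)
        trend = doseresponse.lowess_bootstrap(
            x, y, span=config.span, n_boot=config.n_boot, seed=config.seed
        )
        io.write_trend(out / f"trend_{pheno}.csv", trend)
        ws = doseresponse.gaussian_window_stats(
            x,
            y,
            h=config.half_width,
            n_boot=config.n_boot,
            seed=config.seed,
            half_width_is_fwhm=config.half_width_is_fwhm,
        )
        io.write_window_stats(out / f"var_{pheno}.csv", ws)
    manifest.stages["dose_response"] = "ok"

    config.to_yaml(out / "config.yaml")
    manifest.finished = RunManifest.now()
    manifest.write(out / "manifest.json")
    return cohort
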