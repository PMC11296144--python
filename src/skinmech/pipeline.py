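"""End-to-end analysis runs: records → rheological + elastic-moduli tables,
image pairs → layer-wise strain tables.

Every number in a report is produced by a library operation (stress
conversion, Prony fit, bilinear fit, spectral strain); this module only
orchestrates I/O, grouping and dispersion summaries.  Reports are written as
CSV with the seed and a configuration hash in the header, so re-running the
same configuration reproduces byte-identical files.
"""

from __future__ import annotations

import glob
import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as skio
from .bilinear import LoadingCurve, fit_moduli
from .errors import InvalidInputError, SkinMechError
from .rheology import (
    TestProtocol,
    fit_relaxation_per_cycle,
    mean_prony,
    prony_to_branches,
)
from .spectral import strains_from_pair

__all__ = [
    "DIRECTIONS",
    "RunConfig",
    "ReportTable",
    "load_config",
    "run_relaxation_analysis",
    "run_strain_analysis",
    "make_demo_dataset",
]

logger = logging.getLogger("skinmech")

DIRECTIONS = ("45", "135", "arm-axis", "Langer", "orthogonal")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run (YAML-loadable)."""

    records: tuple[str, ...] = ()
    protocol: TestProtocol = TestProtocol()
    fit_form: str = "standard"
    fit_window: str = "hold_only"
    n_terms: int = 1
    tau_bounds: tuple[float, float] = (1e-2, 1e3)
    min_frac: float = 0.15
    r2_min: float = 0.995
    rest_image: str | None = None
    stretched_image: str | None = None
    roi_file: str | None = None
    direction: str | None = None
    n_areas: int = 1
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.direction is not None and self.direction not in DIRECTIONS:
            raise InvalidInputError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.n_areas < 1:
            raise InvalidInputError("n_areas must be >= 1")

    def digest(self) -> str:
        """Hash of the canonicalized configuration."""
        canon = yaml.safe_dump(_config_dict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _config_dict(cfg: RunConfig) -> dict:
    proto = cfg.protocol
    return {
        "records": list(cfg.records),
        "protocol": {
            "pad_gap_rest_mm": proto.pad_gap_rest_mm,
            "pad_width_mm": proto.pad_width_mm,
            "skin_thickness_mm": proto.skin_thickness_mm,
            "pad_speed_mm_s": proto.pad_speed_mm_s,
            "target_strain": proto.target_strain,
            "hold_time_s": proto.hold_time_s,
            "n_cycles": proto.n_cycles,
        },
        "fit_form": cfg.fit_form, "fit_window": cfg.fit_window,
        "n_terms": cfg.n_terms, "tau_bounds": list(cfg.tau_bounds),
        "min_frac": cfg.min_frac, "r2_min": cfg.r2_min,
        "rest_image": cfg.rest_image, "stretched_image": cfg.stretched_image,
        "roi_file": cfg.roi_file, "direction": cfg.direction,
        "n_areas": cfg.n_areas, "out_dir": cfg.out_dir, "seed": cfg.seed,
        "log_level": cfg.log_level,
    }


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (missing keys take defaults)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    proto = TestProtocol(**doc.pop("protocol", {}))
    records = tuple(doc.pop("records", ()))
    if "tau_bounds" in doc:
        doc["tau_bounds"] = tuple(doc["tau_bounds"])
    return RunConfig(records=records, protocol=proto, **doc)


@dataclass
class ReportTable:
    """A tabular report plus per-column units and per-input error log."""

    df: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)

    def to_csv(self, path, seed: int | None = None,
               config_hash: str | None = None) -> None:
        buf = _io.StringIO()
        buf.write("# generator: skinmech report\n")
        if seed is not None:
            buf.write(f"# seed: {seed}\n")
        if config_hash is not None:
            buf.write(f"# config_sha256: {config_hash}\n")
        if self.units:
            units = ";".join(f"{k}={v}" for k, v in self.units.items())
            buf.write(f"# units: {units}\n")
        for err in self.errors:
            buf.write(f"# error: {err}\n")
        self.df.to_csv(buf, index=False, float_format="%.10g")
        Path(path).write_text(buf.getvalue())

    def summary(self, by: str = "direction", kruskal: bool = False) -> pd.DataFrame:
        """Mean ± s.d. of every numeric column per group; optionally a
        Kruskal–Wallis p-value comparing the groups (delegated to scipy)."""
        num = self.df.select_dtypes("number").columns.difference(["cycle"])
        grouped = self.df.groupby(by)[list(num)]
        out = grouped.agg(["mean", "std"])
        out.columns = [f"{c}_{s}" for c, s in out.columns]
        out = out.reset_index()
        if kruskal:
            from scipy.stats import kruskal as kw

            groups = list(self.df.groupby(by))
            if len(groups) >= 2:
                pvals = {}
                for col in num:
                    samples = [g[col].dropna().to_numpy() for _, g in groups]
                    if all(len(s) >= 2 for s in samples):
                        try:
                            pvals[f"{col}_kw_p"] = kw(*samples).pvalue
                        except ValueError:  # identical values in all groups
                            pvals[f"{col}_kw_p"] = np.nan
                for key, val in pvals.items():
                    out[key] = val
        return out


# ---------------------------------------------------------------------------
# relaxation chain


_RELAX_UNITS = {
    "E0_kPa": "kPa", "E1_kPa": "kPa", "eta1_Pas": "Pa.s", "tau1_s": "s",
    "p1": "1", "E2_kPa": "kPa", "eta2_Pas": "Pa.s", "tau2_s": "s", "p2": "1",
    "E0_inst_kPa": "kPa", "E1_MPa": "MPa", "E2_MPa": "MPa",
    "break_strain": "1", "residual_rms_kPa": "kPa",
}


def _analyze_record(path: str, cfg: RunConfig) -> dict:
    rec, meta = skio.read_record_csv(path, protocol=cfg.protocol)
    rec = rec.to_stress(cfg.protocol.skin_thickness_mm, cfg.protocol.pad_width_mm)
    fits = fit_relaxation_per_cycle(
        rec, fit_window=cfg.fit_window, n_terms=cfg.n_terms,
        form=cfg.fit_form, tau_bounds=cfg.tau_bounds)
    prony = mean_prony(fits)
    branches = prony_to_branches(prony)
    row: dict = {
        "record": Path(path).name,
        "subject": meta.get("subject", Path(path).stem),
        "direction": meta.get("direction", cfg.direction or ""),
        "E0_kPa": branches.E0 / 1e3,
        "E0_inst_kPa": prony.E0 / 1e3,
        "residual_rms_kPa": float(np.mean([f.residual_rms for f in fits])) / 1e3,
        "converged": all(f.converged for f in fits),
    }
    for i, ((E, eta), (p, tau)) in enumerate(zip(branches.branches, prony.terms), 1):
        row[f"E{i}_kPa"] = E / 1e3
        row[f"eta{i}_Pas"] = eta
        row[f"tau{i}_s"] = tau
        row[f"p{i}"] = p
    ramp = rec.mask(cycle=1, phase="ramp")
    curve = LoadingCurve(rec.strain_history[ramp], rec.y[ramp])
    bil = fit_moduli(curve, min_frac=cfg.min_frac, r2_min=cfg.r2_min)
    row["E1_MPa"] = bil.E1 / 1e6
    row["E2_MPa"] = bil.E2 / 1e6
    row["break_strain"] = bil.break_strain
    return row


def run_relaxation_analysis(cfg: RunConfig) -> ReportTable:
    """Per-record stress conversion, per-cycle Prony fits (averaged) and
    bilinear moduli from the first loading ramp.

    Per-file failures are logged and recorded in ``errors``; the run
    continues with the remaining records.
    """
    paths: list[str] = []
    for pattern in cfg.records:
        hits = sorted(glob.glob(pattern))
        paths.extend(hits if hits else [pattern])
    rows, errors = [], []
    for path in paths:
        try:
            rows.append(_analyze_record(path, cfg))
        except (SkinMechError, OSError) as exc:
            msg = f"{path}: {exc}"
            logger.warning(msg)
            errors.append(msg)
    df = pd.DataFrame(rows)
    return ReportTable(df=df, units=dict(_RELAX_UNITS), errors=errors)


# ---------------------------------------------------------------------------
# strain chain


def run_strain_analysis(cfg: RunConfig) -> ReportTable:
    """Layer-wise strains and Poisson's ratio for a rest/stretched image pair.

    With ``n_areas > 1`` each layer ROI is split into that many side-by-side
    areas along x and the per-area dispersion is reported (mean ± s.d.),
    emulating repeated measurements over different regions of one image.
    """
    if not (cfg.rest_image and cfg.stretched_image and cfg.roi_file):
        raise InvalidInputError("strain analysis needs rest/stretched images and a ROI file")
    rois, px, py = skio.read_rois_yaml(cfg.roi_file)
    img0 = skio.read_image(cfg.rest_image, pitch_x=px, pitch_y=py)
    img1 = skio.read_image(cfg.stretched_image, pitch_x=px, pitch_y=py)
    rows, errors = [], []
    for roi in rois:
        areas = [roi] if cfg.n_areas == 1 else _split_roi(roi, cfg.n_areas)
        results = strains_from_pair(img0, img1, areas)
        good = [r.strain for r in results if r.strain is not None]
        for r in results:
            if r.error:
                msg = f"{roi.name}: {r.error}"
                logger.warning(msg)
                errors.append(msg)
        if not good:
            continue
        ex = np.array([s.eps_x for s in good])
        ey = np.array([s.eps_y for s in good])
        nus = np.array([s.nu for s in good if s.nu is not None])
        row = {
            "layer": roi.name,
            "direction": cfg.direction or "arm-axis",
            "eps_x": ex.mean(), "eps_y": ey.mean(),
            "nu": nus.mean() if nus.size else np.nan,
            "n_areas": len(good),
        }
        if len(good) > 1:
            row.update(eps_x_sd=ex.std(ddof=1), eps_y_sd=ey.std(ddof=1),
                       nu_sd=nus.std(ddof=1) if nus.size > 1 else np.nan)
        rows.append(row)
    units = {"eps_x": "1", "eps_y": "1", "nu": "1"}
    return ReportTable(df=pd.DataFrame(rows), units=units, errors=errors)


def _split_roi(roi, n: int):
    from .spectral import LayerROI

    c0, c1 = roi.cols
    width = c1 - c0
    if width < 16 * n:
        raise InvalidInputError(f"ROI '{roi.name}' too narrow for {n} areas")
    edges = np.linspace(c0, c1, n + 1).astype(int)
    return [LayerROI(f"{roi.name}", (roi.rows[0], roi.rows[1]),
                     (int(edges[i]), int(edges[i + 1]))) for i in range(n)]


# ---------------------------------------------------------------------------
# demo fixtures


def make_demo_dataset(outdir, seed: int = 0, n_per_group: int = 6,
                      noise_frac: float = 0.005, dt: float = 0.02) -> dict:
    """Materialize a complete synthetic demo dataset.

    ``2·n_per_group`` synthetic subjects (labelled men/women) each tested in
    the 45° and 135° directions with anisotropy built in per subject, plus a
    layered rest/stretched image pair with the reference layer strains and
    its ROI file, plus a ready-to-run YAML configuration.  Returns the paths.
    """
    from .synthetic import (
        default_layered_spec,
        draw_subject_branches,
        make_layered_image,
        simulate_relaxation_record,
    )

    outdir = Path(outdir)
    (outdir / "records").mkdir(parents=True, exist_ok=True)
    (outdir / "images").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    proto = TestProtocol()
    for idx in range(2 * n_per_group):
        group = "men" if idx < n_per_group else "women"
        params = draw_subject_branches(rng)
        for direction, branches in params.items():
            rec = simulate_relaxation_record(
                branches, proto, noise_frac=noise_frac,
                seed=int(rng.integers(0, 2**31 - 1)), dt=dt)
            name = f"subject{idx + 1:02d}_{direction}.csv"
            skio.write_record_csv(rec, outdir / "records" / name, meta={
                "subject": f"subject{idx + 1:02d}", "group": group,
                "direction": direction})
    spec = default_layered_spec(seed=int(rng.integers(0, 2**31 - 1)))
    rest, stretched, rois = make_layered_image(spec)
    skio.write_image(rest, outdir / "images" / "rest.tif")
    skio.write_image(stretched, outdir / "images" / "stretched.tif")
    skio.write_rois_yaml(rois, outdir / "images" / "rois.yaml",
                         pitch_x=spec.pitch, pitch_y=spec.pitch)
    cfg = RunConfig(records=(str(outdir / "records" / "*.csv"),),
                    rest_image=str(outdir / "images" / "rest.tif"),
                    stretched_image=str(outdir / "images" / "stretched.tif"),
                    roi_file=str(outdir / "images" / "rois.yaml"),
                    direction="arm-axis",
                    out_dir=str(outdir), seed=seed)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(cfg), fh, sort_keys=False)
    return {"config": str(outdir / "config.yaml"),
            "records": str(outdir / "records"),
            "images": str(outdir / "images")}
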