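"""End-to-end orchestration: peak tables -> similarity report -> marker
table -> IC50 table -> activity model, driven by a serializable run config.

Every artifact is CSV or JSON and rounding is applied only at render time,
so a re-run with the same config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import fit_opls, fit_pls
from .errors import FingerqcError, ValidationError
from .io_model import match_common_peaks, read_peak_tables, write_matrix
from .marker_quant import percent_contents, read_contents_csv, summarize_column
from .antioxidant import estimate_ic50, inhibition
from .sqfm import evaluate_matrix, integrate_channels, load_grade_table

log = logging.getLogger("fingerqc")


@dataclass
class RunConfig:
    peak_tables: str
    out_dir: str
    contents: str | None = None
    dpph: str | None = None
    rt_tolerance: float = 0.2
    grade_table: str | None = None
    model_method: str = "pls"
    model_components: int = 2
    cv_folds: int = 7
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sqfm_stage(config: RunConfig, out: Path) -> dict[int, object]:
    tables = read_peak_tables(config.peak_tables)
    by_wl: dict[int, list] = {}
    for t in tables:
        by_wl.setdefault(t.wavelength, []).append(t)
    if config.grade_table is None:
        log.info("no grade table configured; using the built-in default bands")
    grade_table = load_grade_table(config.grade_table)

    matrices = {}
    channel_rows = []
    per_batch: dict[str, list] = {}
    for wl in sorted(by_wl):
        matrix = match_common_peaks(by_wl[wl], rt_tolerance=config.rt_tolerance)
        matrices[wl] = matrix
        write_matrix(matrix, out / f"matrix_{wl}nm.csv", rt_tolerance=config.rt_tolerance)
        for res in evaluate_matrix(matrix, table=grade_table):
            channel_rows.append(res.rounded())
            per_batch.setdefault(res.batch_id, []).append(res)
    pd.DataFrame(channel_rows).to_csv(out / "sqfm_channels.csv", index=False)

    integrated_rows = []
    for batch, results in per_batch.items():
        ig = integrate_channels(results, table=grade_table)
        integrated_rows.append({
            "batch_id": batch,
            "s_m_prime": round(ig.s_m_prime, 2),
            "p_m_prime": round(ig.p_m_prime, 1),
            "alpha_prime": round(ig.alpha_prime, 2),
            "grade": ig.grade,
            "channels": ig.channel_count,
        })
    pd.DataFrame(integrated_rows).to_csv(out / "sqfm_integrated.csv", index=False)
    return matrices


def _marker_stage(config: RunConfig, out: Path) -> None:
    contents = read_contents_csv(config.contents)
    table = percent_contents(contents)
    report = table.to_frame().round(1)
    summary = {
        m: summarize_column(contents[m].to_numpy()) for m in contents.columns
    }
    report.loc["Mean"] = [round(summary[m][0], 2) for m in contents.columns] + [100.0]
    report.loc["RSD(%)"] = [round(summary[m][1], 1) for m in contents.columns] + [
        round(float(np.std(table.p7c, ddof=1) / np.mean(table.p7c) * 100), 1)
    ]
    report.to_csv(out / "marker_contents.csv")


def _dpph_stage(config: RunConfig, out: Path) -> pd.Series:
    df = pd.read_csv(config.dpph)
    rows = []
    for batch, grp in df.groupby("batch_id", sort=False):
        inh = [inhibition(r.a_control, r.a_sample) for r in grp.itertuples()]
        res = estimate_ic50(grp["concentration_mg_ml"].to_numpy(), np.array(inh),
                            batch_id=str(batch))
        rows.append({"batch_id": batch, "ic50_mg_ml": res.ic50,
                     "inv_ic50": 1.0 / res.ic50, "extrapolated": res.extrapolated})
    frame = pd.DataFrame(rows)
    frame.round(4).to_csv(out / "ic50.csv", index=False)
    return frame.set_index("batch_id")["inv_ic50"]


def _model_stage(config: RunConfig, matrices, response: pd.Series, out: Path) -> None:
    wl = sorted(matrices)[0]
    matrix = matrices[wl]
    y = response.reindex(matrix.batch_ids)
    if y.isna().any():
        raise ValidationError(f"missing response for batches {list(y[y.isna()].index)}")
    fitter = fit_pls if config.model_method == "pls" else fit_opls
    kwargs = (
        {"n_components": config.model_components}
        if config.model_method == "pls"
        else {"n_orthogonal": max(0, config.model_components - 1)}
    )
    model = fitter(matrix.areas, y.to_numpy(), cv_folds=config.cv_folds,
                   seed=config.seed, **kwargs)
    payload = model.to_dict()
    payload["wavelength"] = wl
    payload["peak_ids"] = matrix.peak_ids
    payload["cv_folds"] = config.cv_folds
    payload["seed"] = config.seed
    (out / "model.json").write_text(json.dumps(payload, indent=2))


def run_pipeline(config: RunConfig) -> Path:
    """Run all configured stages; returns the output directory.

    Stage failures abort with the stage name prefixed so the operator can
    locate the offending input.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run config digest %s", config.digest())
    response = None
    matrices = None
    for stage, enabled, fn in [
        ("sqfm", True, lambda: _sqfm_stage(config, out)),
        ("markers", config.contents is not None, lambda: _marker_stage(config, out)),
        ("dpph", config.dpph is not None, lambda: _dpph_stage(config, out)),
    ]:
        if not enabled:
            log.info("stage %s skipped (no input configured)", stage)
            continue
        try:
            result = fn()
        except FingerqcError as exc:
            raise type(exc)(f"stage {stage}: {exc}") from exc
        if stage == "sqfm":
            matrices = result
        elif stage == "dpph":
            response = result
    if response is not None and matrices:
        try:
            _model_stage(config, matrices, response, out)
        except FingerqcError as exc:
            raise type(exc)(f"stage model: {exc}") from exc
    (out / "run_log.json").write_text(json.dumps({
        "version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
    }, indent=2))
    return out
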