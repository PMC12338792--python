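"""Study-level synthetic data: per-mouse metric trajectories and
volume-backed study fixtures.

Each mouse carries a random intercept around its group's baseline; the group
mean drifts linearly from baseline to a month-7 target (per site), and each
visit adds independent measurement noise. Defaults encode a back-site-only
photodamage effect: dermal attenuation falls from ~40 mm^-1 toward the
20-33 mm^-1 band in the UVR groups while skin thickens, and the side and
stomach sites stay flat for every group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GROUPS,
    SITES,
    StudyRecord,
    write_annotations,
    write_study_table,
    write_volume,
)
from .phantom import default_phantom, generate_volume, reference_annotations
from .stats import MetricSeries


@dataclass(frozen=True)
class MetricModel:
    """Linear-drift trajectory of one metric.

    ``month7`` maps (group, site) to the month-7 group mean; combinations
    not listed stay at baseline. ``sigma_mouse`` is the between-animal
    standard deviation (random intercept), ``sigma_visit`` the per-visit
    measurement noise.
    """

    baseline: float
    month7: Mapping[tuple[str, str], float]
    sigma_mouse: float
    sigma_visit: float

    def mean_at(self, group: str, site: str, month: int) -> float:
        target = self.month7.get((group, site), self.baseline)
        return self.baseline + (target - self.baseline) * month / 7.0


def attenuation_model(delta_back: Mapping[str, float] | None = None) -> MetricModel:
    """Default dermal-attenuation trajectory (mm^-1).

    Baseline 40 for all groups; at month 7 the back site of the UVR groups
    has dropped into the 20-33 band (UVR control lowest, NMN-treated
    highest among them). ``delta_back`` can override the month-7 back-site
    targets per group.
    """
    month7 = {
        ("uvr_control", "back"): 23.0,
        ("uvr_nmn", "back"): 31.0,
        ("uvr_pl", "back"): 26.0,
    }
    if delta_back is not None:
        month7 = {(g, "back"): v for g, v in delta_back.items()}
    return MetricModel(baseline=40.0, month7=month7, sigma_mouse=2.0, sigma_visit=1.2)


def thickness_model() -> MetricModel:
    """Default combined epidermis+dermis thickness trajectory (um):
    baseline 420 um, UVR-driven thickening at the back only."""
    return MetricModel(
        baseline=420.0,
        month7={
            ("uvr_control", "back"): 560.0,
            ("uvr_nmn", "back"): 525.0,
            ("uvr_pl", "back"): 540.0,
        },
        sigma_mouse=25.0,
        sigma_visit=12.0,
    )


def null_model(baseline: float = 40.0, sigma_mouse: float = 2.0,
               sigma_visit: float = 1.2) -> MetricModel:
    """No group effect anywhere: every group/site/month shares one mean."""
    return MetricModel(baseline=baseline, month7={}, sigma_mouse=sigma_mouse,
                       sigma_visit=sigma_visit)


def generate_metric_series(
    metric: str,
    model: MetricModel,
    rng: np.random.Generator,
    n_mice: int = 6,
    months: Sequence[int] = tuple(range(8)),
    groups: Sequence[str] = GROUPS,
    sites: Sequence[str] = SITES,
) -> MetricSeries:
    """Draw a long-format metric table directly from the trajectory model
    (no volumes involved) — the fast path for plan-level simulation."""
    rows = []
    for group in groups:
        for i in range(n_mice):
            mouse = f"{group}_m{i}"
            intercept = rng.normal(0.0, model.sigma_mouse)
            for site in sites:
                for month in months:
                    value = (
                        model.mean_at(group, site, month)
                        + intercept
                        + rng.normal(0.0, model.sigma_visit)
                    )
                    rows.append(
                        {
                            "mouse_id": mouse,
                            "group": group,
                            "site": site,
                            "month": int(month),
                            "value": value,
                        }
                    )
    return MetricSeries(metric=metric, records=pd.DataFrame(rows))


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0]) % (2**31)


def generate_study(
    out_dir: str | Path,
    seed: int = 0,
    n_mice: int = 6,
    months: Sequence[int] = tuple(range(8)),
    groups: Sequence[str] = GROUPS,
    sites: Sequence[str] = SITES,
    mu_model: MetricModel | None = None,
    th_model: MetricModel | None = None,
    phantom_overrides: Mapping | None = None,
) -> tuple[Path, list[StudyRecord]]:
    """Write a volume-backed synthetic study to ``out_dir``.

    Emits one phantom volume per (mouse, site, month) whose dermal
    attenuation and dermis thickness follow the trajectory models, a study
    table CSV, a ground-truth CSV of the true per-record values, and one
    flat (jitter-free) calibration reference volume per group at baseline
    with air/muscle annotations — mirroring a reference set of one dataset
    per group.
    """
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    (out_dir / "references").mkdir(parents=True, exist_ok=True)
    mu_model = mu_model or attenuation_model()
    th_model = th_model or thickness_model()
    overrides = dict(phantom_overrides or {})
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    records, truth_rows = [], []
    for group in groups:
        for i in range(n_mice):
            mouse = f"{group}_m{i}"
            mu_int = rng.normal(0.0, mu_model.sigma_mouse)
            th_int = rng.normal(0.0, th_model.sigma_mouse)
            for site in sites:
                for month in months:
                    mu_true = float(
                        np.clip(
                            mu_model.mean_at(group, site, month)
                            + mu_int
                            + rng.normal(0.0, mu_model.sigma_visit),
                            5.0,
                            80.0,
                        )
                    )
                    th_true = float(
                        np.clip(
                            th_model.mean_at(group, site, month)
                            + th_int
                            + rng.normal(0.0, th_model.sigma_visit),
                            120.0,
                            700.0,
                        )
                    )
                    spec = default_phantom(
                        dermal_attenuation=mu_true,
                        dermis_thickness=th_true - 20.0,  # 20 um epidermis
                        seed=_child_seed(root.spawn(1)[0]),
                        **overrides,
                    )
                    vol, _ = generate_volume(spec)
                    name = f"{mouse}_{site}_m{month}.tif"
                    path = out_dir / "volumes" / name
                    vol.source_id = name
                    write_volume(vol, path)
                    records.append(
                        StudyRecord(mouse, group, site, int(month), str(path))
                    )
                    truth_rows.append(
                        {
                            "mouse_id": mouse,
                            "group": group,
                            "site": site,
                            "month": int(month),
                            "true_mu_mm_inv": mu_true,
                            "true_thickness_um": th_true,
                        }
                    )

    # Flat baseline reference volumes, one per group, for calibration.
    annotations = []
    for group in groups:
        ref_spec = default_phantom(
            dermal_attenuation=mu_model.baseline,
            seed=_child_seed(root.spawn(1)[0]),
            thickness_jitter=0.0,
            **overrides,
        )
        ref_vol, _ = generate_volume(ref_spec)
        ref_name = f"reference_{group}.tif"
        ref_vol.source_id = ref_name
        ref_path = out_dir / "references" / ref_name
        write_volume(ref_vol, ref_path)
        annotations.extend(reference_annotations(ref_spec, str(ref_path)))
    write_annotations(annotations, out_dir / "references" / "annotations.json")

    table_path = write_study_table(records, out_dir / "study_table.csv")
    pd.DataFrame(truth_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    return table_path, records
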