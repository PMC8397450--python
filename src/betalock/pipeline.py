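"""End-to-end paradigm analyses over a generated or recorded cohort.

Each ``run_*`` function loads every subject's session from a cohort
directory (see :func:`betalock.synthetic_data.gen_cohort` for the layout),
derives behavioral segmentations and spectral estimates, and assembles the
group-level report tables: time budgets and their contrasts for the
cylinder test, locomotion features and speed-power tables for the open
field, and fall-time comparisons plus forced-speed power analysis for the
rotarod.

Every output table carries the cohort config hash and software version;
re-running on identical inputs yields identical CSV bytes.  Subjects whose
session lacks a required stream are skipped with a logged reason rather
than aborting the whole analysis.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    compute_speed,
    openfield_features,
    rotarod_profile,
    segment_states,
    time_budget,
)
from .core_io import (
    BANDS,
    SessionBundle,
    StateIntervals,
    ValidationError,
    read_session,
)
from .group_stats import (
    ed_condition_compare,
    kendall_correlation,
    per_speed_significance,
    pooled_speed_power,
    rank_sum_compare,
    state_band_compare,
)
from .spectral import band_power, multitaper_psd, state_locked_psd
from .synthetic_data import rod_speed_cm_s

__all__ = [
    "clip_states",
    "windowed_band_power",
    "run_cylinder",
    "run_openfield",
    "run_rotarod",
]

_BAND_NAMES = ("theta", "low_beta", "high_beta")


def clip_states(states: StateIntervals, t0: float, t1: float) -> StateIntervals:
    """Restrict a state partition to the window [t0, t1)."""
    out = []
    for a, b, s in states.intervals:
        lo, hi = max(a, t0), min(b, t1)
        if hi > lo:
            out.append((lo, hi, s))
    if not out:
        raise ValidationError(f"no states overlap window [{t0}, {t1})")
    return StateIntervals(out)


def windowed_band_power(
    x: np.ndarray,
    fs: float,
    band,
    window: float = 5.0,
    t0: float = 0.0,
    normalize: str = "relative",
) -> tuple[np.ndarray, np.ndarray]:
    """(window_starts, band power per non-overlapping window)."""
    n_win = int(x.size / (window * fs))
    per = int(round(window * fs))
    starts = t0 + np.arange(n_win) * window
    vals = np.empty(n_win)
    for k in range(n_win):
        psd = multitaper_psd(x[k * per : (k + 1) * per], fs, min_duration=window)
        vals[k] = band_power(psd, band, normalize)
    return starts, vals


def _config_hash(cohort_dir: Path, params: dict) -> str:
    h = hashlib.sha256()
    manifest = cohort_dir / "manifest.csv"
    if manifest.exists():
        h.update(manifest.read_bytes())
    h.update(json.dumps(params, sort_keys=True, default=str).encode())
    return h.hexdigest()[:12]


def _write_reports(
    reports: dict[str, pd.DataFrame], out_dir: Path | None, cfg_hash: str, log: list[str]
) -> None:
    if out_dir is None:
        return
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in reports.items():
        if not isinstance(df, pd.DataFrame):
            continue
        df = df.copy()
        df["config_hash"] = cfg_hash
        df["version"] = __version__
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.6g",
                  lineterminator="\n")
    (out_dir / "run_meta.json").write_text(
        json.dumps({"config_hash": cfg_hash, "version": __version__, "log": log},
                   indent=2, sort_keys=True)
        + "\n"
    )


def _load_cohort(cohort_dir: str | Path, paradigm: str) -> tuple[pd.DataFrame, dict, list[str]]:
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    sessions: dict[str, SessionBundle] = {}
    log: list[str] = []
    for rec in manifest.itertuples():
        sdir = cohort_dir / rec.subject_id / paradigm
        if not sdir.exists():
            log.append(f"skip {rec.subject_id}: no {paradigm} session directory")
            continue
        try:
            sessions[rec.subject_id] = read_session(sdir)
        except (ValidationError, OSError) as exc:
            log.append(f"skip {rec.subject_id}: {exc}")
    return manifest, sessions, log


def _tests_df(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["contrast", "state", "band", "statistic", "p", "n_a", "n_b",
                 "significant"],
    )


# ---------------------------------------------------------------------------
# cylinder
# ---------------------------------------------------------------------------

def run_cylinder(
    cohort_dir: str | Path,
    out_dir: str | Path | None = None,
    region: str = "M1",
    normalize: str = "raw",
    alpha: float = 0.05,
    ed_mode: str = "printed",
    window_len: float = 2.0,
) -> dict:
    """Cylinder-test analysis: time budgets, state-locked spectra, ED tables.

    Behavioral contrasts follow the published design: sham minute 1 vs
    minute 2, PD vs sham in minute 1, and the three-group comparison in
    minute 2.  Hemisphere band-power contrasts use minute 1 (stimulation-free
    for every subject); the distance-to-sham comparison of the two DBS
    conditions uses minute 2, when the stimulated subgroup receives DBS.

    The hemisphere contrast is within-animal, so it defaults to raw band
    power (``normalize="raw"``); relative power divides out the per-animal
    amplitude scale that makes this contrast robust.  The ``band_power``
    report carries both variants.
    """
    cohort_dir = Path(cohort_dir)
    manifest, sessions, log = _load_cohort(cohort_dir, "cylinder")
    assignment = dict(zip(manifest["subject_id"], manifest["assignment"]))
    group_of = dict(zip(manifest["subject_id"], manifest["group"]))

    budget_rows = []
    psd_rows = []  # minute-1 state-locked PSDs, both hemispheres
    ed_psds: dict[str, dict[str, list]] = {
        bn: {"PD-DBS ON": [], "PD-DBS OFF": [], "sham": []} for bn in ("low_beta", "high_beta")
    }
    for sid, bundle in sorted(sessions.items()):
        if bundle.codes is None or bundle.rotation is None:
            log.append(f"skip {sid}: missing codes/rotation streams")
            continue
        if bundle.lfp is None:
            log.append(f"skip {sid}: missing LFP")
            continue
        states = segment_states(bundle.codes, bundle.rotation)
        for minute, (w0, w1) in enumerate([(0.0, 60.0), (60.0, 120.0)], start=1):
            tb = time_budget(states, (w0, min(w1, states.end)))
            budget_rows.append(
                {"subject_id": sid, "group": group_of[sid],
                 "assignment": assignment[sid], "minute": minute, **tb}
            )
        # stimulation-free state-locked spectra for hemisphere contrasts:
        # all DBS-off episodes (minute 1 only for the stimulated subgroup)
        off_end = states.end
        for e in bundle.config.episodes:
            if e.dbs_on:
                off_end = min(off_end, e.start)
        m1_states = clip_states(states, 0.0, off_end)
        for hemi in ("left", "right"):
            try:
                ch = bundle.lfp.select(region=region, hemisphere=hemi)
            except ValidationError as exc:
                log.append(f"skip {sid}/{hemi}: {exc}")
                continue
            for state in ("rearing", "stepping", "inactive"):
                try:
                    psd = state_locked_psd(
                        ch, m1_states, state,
                        min_episode=window_len, window_len=window_len,
                    )
                except ValidationError as exc:
                    log.append(f"{sid}/{hemi}/{state}: {exc}")
                    continue
                psd_rows.append(
                    {"subject_id": sid, "group": group_of[sid], "hemisphere": hemi,
                     "state": state, "psd": psd, "n_windows": psd.meta["n_windows"]}
                )
        # minute-2 rearing spectra (lesioned side for PD, right for sham)
        m2_states = clip_states(states, 60.0, states.end)
        try:
            ch = bundle.lfp.select(region=region, hemisphere="right")
            psd2 = state_locked_psd(
                ch, m2_states, "rearing",
                min_episode=window_len, window_len=window_len,
            )
            for bn in ed_psds:
                ed_psds[bn][assignment[sid]].append(psd2)
        except ValidationError as exc:
            log.append(f"{sid}/minute2 rearing: {exc}")

    budgets = pd.DataFrame(budget_rows)
    psd_table = pd.DataFrame(psd_rows)

    # behavioral contrasts
    test_rows = []

    def _budget_vals(mask, minute, state):
        sel = budgets[(mask) & (budgets["minute"] == minute)]
        return sel[state].to_numpy()

    sham_mask = budgets["group"] == "sham"
    pd_mask = budgets["group"] == "PD"
    on_mask = budgets["assignment"] == "PD-DBS ON"
    off_mask = budgets["assignment"] == "PD-DBS OFF"
    contrasts = [
        ("sham_min1_vs_min2", sham_mask, 1, sham_mask, 2),
        ("pd_vs_sham_min1", pd_mask, 1, sham_mask, 1),
        ("sham_vs_pd_on_min2", sham_mask, 2, on_mask, 2),
        ("sham_vs_pd_off_min2", sham_mask, 2, off_mask, 2),
        ("pd_on_vs_pd_off_min2", on_mask, 2, off_mask, 2),
    ]
    for name, mask_a, min_a, mask_b, min_b in contrasts:
        for state in ("rearing", "stepping", "inactive"):
            a = _budget_vals(mask_a, min_a, state)
            b = _budget_vals(mask_b, min_b, state)
            if a.size < 2 or b.size < 2:
                continue
            res = rank_sum_compare(a, b, mode="approx")
            test_rows.append(
                {"contrast": name, "state": state, "band": "", "statistic": res.statistic,
                 "p": res.p_value, "n_a": res.n_a, "n_b": res.n_b,
                 "significant": res.p_value < alpha}
            )

    # hemisphere band-power contrasts (the 9-cell pattern + sham control)
    band_rows = []
    fig9_rows = []
    for state in ("rearing", "stepping", "inactive"):
        st_tab = psd_table[psd_table["state"] == state] if not psd_table.empty else psd_table
        for bn in _BAND_NAMES:
            band = BANDS[bn]
            if not st_tab.empty:
                for rec in st_tab.itertuples():
                    band_rows.append(
                        {"subject_id": rec.subject_id, "group": rec.group,
                         "hemisphere": rec.hemisphere, "state": state, "band": bn,
                         "power_raw": band_power(rec.psd, band, "raw"),
                         "power_rel": band_power(rec.psd, band, "relative")}
                    )
            for contrast in ("lesioned_vs_intact", "sham_left_vs_right"):
                try:
                    res = state_band_compare(st_tab, band, contrast, normalize)
                except (ValidationError, KeyError) as exc:
                    log.append(f"{contrast}/{state}/{bn}: {exc}")
                    continue
                fig9_rows.append(
                    {"contrast": contrast, "state": state, "band": bn,
                     "statistic": res.statistic, "p": res.p_value,
                     "n_a": res.n_a, "n_b": res.n_b,
                     "significant": res.p_value < alpha}
                )

    # ED condition comparison (minute 2, rearing)
    ed_rows = []
    ed_test_rows = []
    for bn, conds in ed_psds.items():
        try:
            df_ed, res = ed_condition_compare(conds, BANDS[bn], mode=ed_mode)
        except ValidationError as exc:
            log.append(f"ED/{bn}: {exc}")
            continue
        ed_rows.append(df_ed)
        ed_test_rows.append(
            {"contrast": "ed_off_vs_on", "state": "rearing", "band": bn,
             "statistic": res.statistic, "p": res.p_value, "n_a": res.n_a,
             "n_b": res.n_b, "significant": res.p_value < alpha}
        )

    reports = {
        "budgets": budgets,
        "behavior_tests": _tests_df(test_rows),
        "band_power": pd.DataFrame(band_rows),
        "hemisphere_tests": _tests_df(fig9_rows),
        "ed_values": pd.concat(ed_rows, ignore_index=True) if ed_rows else pd.DataFrame(),
        "ed_tests": _tests_df(ed_test_rows),
    }
    cfg_hash = _config_hash(cohort_dir, {"paradigm": "cylinder", "region": region,
                                         "normalize": normalize, "alpha": alpha,
                                         "ed_mode": ed_mode})
    _write_reports(reports, Path(out_dir) if out_dir else None, cfg_hash, log)
    reports["log"] = log
    reports["psd_table"] = psd_table
    return reports


# ---------------------------------------------------------------------------
# open field
# ---------------------------------------------------------------------------

def run_openfield(
    cohort_dir: str | Path,
    out_dir: str | Path | None = None,
    region: str = "M1",
    hemisphere: str = "right",
    normalize: str = "relative",
    alpha: float = 0.05,
    window: float = 5.0,
    min_count: int = 5,
) -> dict:
    """Open-field analysis: locomotion features and the speed-power tables.

    Features (average velocity, large-movement time, distance, immobility)
    are computed per episode and contrasted between groups; band power over
    non-overlapping 5-s windows is pooled per group and related to window
    speed (1-16 cm/s bins, Kendall correlation, per-bin rank-sum tests).
    Windows straddling a DBS episode boundary are discarded.
    """
    cohort_dir = Path(cohort_dir)
    manifest, sessions, log = _load_cohort(cohort_dir, "openfield")
    assignment = dict(zip(manifest["subject_id"], manifest["assignment"]))
    group_of = dict(zip(manifest["subject_id"], manifest["group"]))

    feat_rows = []
    windows_by_group: dict[str, dict[str, list[pd.DataFrame]]] = {}
    for sid, bundle in sorted(sessions.items()):
        if bundle.tracking is None:
            log.append(f"skip {sid}: missing tracking")
            continue
        speed = compute_speed(bundle.tracking)
        fps = bundle.tracking.fps
        episodes = [(e.start, e.end, e.dbs_on) for e in bundle.config.episodes]
        feats = openfield_features(speed, fps, episodes, t0=bundle.tracking.t0)
        for k, ef in enumerate(feats.per_episode, start=1):
            feat_rows.append(
                {"subject_id": sid, "group": group_of[sid],
                 "assignment": assignment[sid], "episode": k, "dbs_on": ef.dbs_on,
                 "avg_velocity": ef.avg_velocity, "lm_time": ef.lm_time,
                 "immobility_time": ef.immobility_time, "distance": ef.distance}
            )
        if bundle.lfp is None:
            log.append(f"{sid}: no LFP; skipping speed-power")
            continue
        try:
            ch = bundle.lfp.select(region=region, hemisphere=hemisphere)
        except ValidationError as exc:
            log.append(f"{sid}: {exc}")
            continue
        for bn in _BAND_NAMES:
            starts, vals = windowed_band_power(
                ch.samples[0], ch.sample_rate, BANDS[bn], window=window,
                t0=ch.t0, normalize=normalize,
            )
            per_frame = int(round(window * fps))
            rows = []
            for k, t_start in enumerate(starts):
                # discard windows that straddle a DBS episode boundary
                if not any(e.start <= t_start and t_start + window <= e.end
                           for e in bundle.config.episodes):
                    continue
                i0 = int(round((t_start - bundle.tracking.t0) * fps))
                s_mean = float(speed[i0 : i0 + per_frame].mean())
                rows.append({"window_start": t_start, "speed": s_mean,
                             "speed_bin": float(np.floor(s_mean)), "power": vals[k],
                             "subject_id": sid})
            wdf = pd.DataFrame(rows,
                               columns=["window_start", "speed", "speed_bin",
                                        "power", "subject_id"])
            windows_by_group.setdefault(bn, {}).setdefault(group_of[sid], []).append(wdf)

    features = pd.DataFrame(feat_rows)

    # feature contrasts per episode
    test_rows = []
    feature_cols = ("avg_velocity", "lm_time", "immobility_time", "distance")
    if not features.empty:
        for episode in sorted(features["episode"].unique()):
            ep = features[features["episode"] == episode]
            pairs = [
                ("sham_vs_pd", ep["group"] == "sham", ep["group"] == "PD"),
                ("sham_vs_pd_on", ep["group"] == "sham", ep["assignment"] == "PD-DBS ON"),
                ("sham_vs_pd_off", ep["group"] == "sham", ep["assignment"] == "PD-DBS OFF"),
                ("pd_on_vs_pd_off", ep["assignment"] == "PD-DBS ON",
                 ep["assignment"] == "PD-DBS OFF"),
            ]
            for name, ma, mb in pairs:
                for col in feature_cols:
                    a, b = ep.loc[ma, col].to_numpy(), ep.loc[mb, col].to_numpy()
                    if a.size < 2 or b.size < 2:
                        continue
                    res = rank_sum_compare(a, b, mode="approx")
                    test_rows.append(
                        {"contrast": f"ep{episode}_{name}", "state": col, "band": "",
                         "statistic": res.statistic, "p": res.p_value,
                         "n_a": res.n_a, "n_b": res.n_b,
                         "significant": res.p_value < alpha}
                    )

    # speed-power tables and per-speed significance
    sp_tables = []
    sp_sig = []
    corr_rows = []
    for bn, by_group in windows_by_group.items():
        spts = {}
        for grp, frames in by_group.items():
            spt = pooled_speed_power(frames, min_count=min_count, group=grp)
            spt.table["band"] = bn
            spts[grp] = spt
            sp_tables.append(spt.table)
            w = spt.windows
            if len(w) >= 3 and w["speed"].nunique() > 1 and w["power"].nunique() > 1:
                res = kendall_correlation(w["speed"], w["power"])
                corr_rows.append({"band": bn, "group": grp, "tau": res.tau,
                                  "p": res.p_value, "n": res.n_a})
        if "PD" in spts and "sham" in spts:
            sig = per_speed_significance(spts["PD"], spts["sham"], alpha=alpha)
            sig["band"] = bn
            sp_sig.append(sig)

    reports = {
        "features": features,
        "feature_tests": _tests_df(test_rows),
        "speed_power": pd.concat(sp_tables, ignore_index=True) if sp_tables else pd.DataFrame(),
        "speed_power_tests": pd.concat(sp_sig, ignore_index=True) if sp_sig else pd.DataFrame(),
        "speed_power_correlation": pd.DataFrame(corr_rows),
    }
    cfg_hash = _config_hash(cohort_dir, {"paradigm": "openfield", "region": region,
                                         "hemisphere": hemisphere,
                                         "normalize": normalize, "alpha": alpha})
    _write_reports(reports, Path(out_dir) if out_dir else None, cfg_hash, log)
    reports["log"] = log
    return reports


# ---------------------------------------------------------------------------
# rotarod
# ---------------------------------------------------------------------------

def run_rotarod(
    cohort_dir: str | Path,
    out_dir: str | Path | None = None,
    region: str = "M1",
    hemisphere: str = "right",
    normalize: str = "relative",
    alpha: float = 0.05,
    window: float = 5.0,
    min_count: int = 5,
) -> dict:
    """Rotarod analysis: fall-time contrasts and forced-speed power tables.

    Rounds 1-2 are stimulation-free for everyone (PD vs sham contrast);
    round 3 splits the lesioned group into DBS-ON and DBS-OFF.  The
    speed-power analysis uses the rod's ramp speed (converted to cm/s at the
    rod surface) in place of tracked locomotion speed.
    """
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    assignment = dict(zip(manifest["subject_id"], manifest["assignment"]))
    group_of = dict(zip(manifest["subject_id"], manifest["group"]))
    log: list[str] = []

    outcome_rows = []
    windows_by_group: dict[str, dict[str, list[pd.DataFrame]]] = {}
    profile = rotarod_profile("test")
    for sid in manifest["subject_id"]:
        oc_path = cohort_dir / sid / "rotarod.csv"
        if not oc_path.exists():
            log.append(f"skip {sid}: no rotarod outcomes")
            continue
        oc = pd.read_csv(oc_path)
        for rec in oc.itertuples():
            outcome_rows.append(
                {"subject_id": sid, "group": group_of[sid],
                 "assignment": assignment[sid], "round": int(rec.round),
                 "time_on_rod_s": float(rec.time_on_rod_s),
                 "max_speed_rpm": float(rec.max_speed_rpm),
                 "dbs_on": bool(rec.dbs_on)}
            )
            sdir = cohort_dir / sid / f"rotarod_r{int(rec.round)}"
            if int(rec.round) > 2 or not (sdir / "lfp.h5").exists():
                continue  # speed-power pools the stimulation-free rounds only
            try:
                bundle = read_session(sdir)
                ch = bundle.lfp.select(region=region, hemisphere=hemisphere)
            except (ValidationError, OSError) as exc:
                log.append(f"{sid} r{rec.round}: {exc}")
                continue
            for bn in _BAND_NAMES:
                starts, vals = windowed_band_power(
                    ch.samples[0], ch.sample_rate, BANDS[bn], window=window,
                    t0=ch.t0, normalize=normalize,
                )
                centers = starts + window / 2.0
                speeds = rod_speed_cm_s([profile.speed_at(t) for t in centers])
                wdf = pd.DataFrame(
                    {"window_start": starts, "speed": speeds,
                     "speed_bin": np.floor(speeds), "power": vals,
                     "subject_id": sid}
                )
                windows_by_group.setdefault(bn, {}).setdefault(
                    group_of[sid], []
                ).append(wdf)

    outcomes = pd.DataFrame(outcome_rows)
    test_rows = []
    if not outcomes.empty:
        r12 = outcomes[outcomes["round"] <= 2]
        a = r12.loc[r12["group"] == "sham", "time_on_rod_s"].to_numpy()
        b = r12.loc[r12["group"] == "PD", "time_on_rod_s"].to_numpy()
        if a.size >= 2 and b.size >= 2:
            res = rank_sum_compare(a, b, mode="approx")
            test_rows.append(
                {"contrast": "rounds12_sham_vs_pd", "state": "time_on_rod", "band": "",
                 "statistic": res.statistic, "p": res.p_value, "n_a": res.n_a,
                 "n_b": res.n_b, "significant": res.p_value < alpha}
            )
        r3 = outcomes[outcomes["round"] == 3]
        pairs = [
            ("r3_sham_vs_pd_on", r3["group"] == "sham",
             r3["assignment"] == "PD-DBS ON"),
            ("r3_sham_vs_pd_off", r3["group"] == "sham",
             r3["assignment"] == "PD-DBS OFF"),
            ("r3_pd_on_vs_pd_off", r3["assignment"] == "PD-DBS ON",
             r3["assignment"] == "PD-DBS OFF"),
        ]
        for name, ma, mb in pairs:
            a = r3.loc[ma, "time_on_rod_s"].to_numpy()
            b = r3.loc[mb, "time_on_rod_s"].to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            res = rank_sum_compare(a, b, mode="approx")
            test_rows.append(
                {"contrast": name, "state": "time_on_rod", "band": "",
                 "statistic": res.statistic, "p": res.p_value, "n_a": res.n_a,
                 "n_b": res.n_b, "significant": res.p_value < alpha}
            )

    sp_tables, sp_sig, corr_rows = [], [], []
    for bn, by_group in windows_by_group.items():
        spts = {}
        for grp, frames in by_group.items():
            spt = pooled_speed_power(frames, min_count=min_count, group=grp)
            spt.table["band"] = bn
            spts[grp] = spt
            sp_tables.append(spt.table)
            w = spt.windows
            if len(w) >= 3 and w["speed"].nunique() > 1 and w["power"].nunique() > 1:
                res = kendall_correlation(w["speed"], w["power"])
                corr_rows.append({"band": bn, "group": grp, "tau": res.tau,
                                  "p": res.p_value, "n": res.n_a})
        if "PD" in spts and "sham" in spts:
            sig = per_speed_significance(spts["PD"], spts["sham"], alpha=alpha)
            sig["band"] = bn
            sp_sig.append(sig)

    reports = {
        "outcomes": outcomes,
        "outcome_tests": _tests_df(test_rows),
        "speed_power": pd.concat(sp_tables, ignore_index=True) if sp_tables else pd.DataFrame(),
        "speed_power_tests": pd.concat(sp_sig, ignore_index=True) if sp_sig else pd.DataFrame(),
        "speed_power_correlation": pd.DataFrame(corr_rows),
    }
    cfg_hash = _config_hash(cohort_dir, {"paradigm": "rotarod", "region": region,
                                         "hemisphere": hemisphere,
                                         "normalize": normalize, "alpha": alpha})
    _write_reports(reports, Path(out_dir) if out_dir else None, cfg_hash, log)
    reports["log"] = log
    return reports
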