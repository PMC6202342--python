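"""Configuration-driven orchestration of the full analysis chain.

Stages: ``simulate`` (synthetic study) -> ``preprocess`` (artifact and
clinical exclusions) -> ``connect`` (coherence + distance networks) ->
``evoked`` (band-power contrasts) -> ``nma`` (per-site permutation
statistic) -> ``group`` (white-matter trend, directional counts, whole-
brain summaries). Every stochastic stage has an explicit seed; a report
records every exclusion with its reason and a hash of the configuration
and of the results, so identical configs reproduce identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as snio
from .connectivity import coherence_network, distance_network
from .errors import TooFewElectrodesError
from .evoked import BANDS, session_power_contrast, whole_brain_power_change
from .group import (
    classify_wm,
    directional_count_test,
    group_onesample_test,
    wm_trend_permutation_test,
)
from .nma import compute_nma
from .recording import apply_exclusions, cut_windows, detect_artifact_channels
from .spectral import MultitaperSpec
from .synthetic import generate_study, make_ground_truth

log = logging.getLogger("stimnet")

STAGES = ("simulate", "preprocess", "connect", "evoked", "nma", "group")


@dataclass
class RunConfig:
    """Everything a reproducible run needs; no hidden defaults downstream."""

    out_dir: str = "stimnet_out"
    stages: tuple[str, ...] = STAGES
    n_electrodes: int = 60
    n_sites: int = 3
    n_trials: int = 240
    n_baseline_periods: int = 10
    fs: float = 1000.0
    n_perm: int = 1000
    alpha: float = 0.05
    line_freq: float = 60.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: b.edges for k, b in BANDS.items()}
    )
    time_bandwidth: float = 4.0
    max_tapers: int = 8
    min_concentration: float = 0.9
    wm_direction: str = "near_is_close"
    perm_mode: str = "joint"  # or "connectivity"
    seeds: dict[str, int] = field(
        default_factory=lambda: {"simulate": 1, "nma": 2, "group": 3}
    )
    # planted-effect overrides for the simulate stage (None = generator default)
    beta_conn: float | None = None
    beta_dist: float | None = None
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name!r} has invalid edges ({lo}, {hi})")
        for stage in ("simulate", "nma", "group"):
            if stage not in self.seeds:
                raise ValueError(f"missing seed for stochastic stage {stage!r}")
        if self.n_perm < 100:
            log.warning("n_perm=%d < 100: permutation z-scores will be unstable", self.n_perm)

    @property
    def mt_spec(self) -> MultitaperSpec:
        return MultitaperSpec(self.time_bandwidth, self.max_tapers, self.min_concentration)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path, strict: bool = True) -> RunConfig:
    """Load a YAML or JSON run configuration, filling documented defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        if strict:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in unknown:
            data.pop(k)
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    if "bands" in data:
        data["bands"] = {k: tuple(v) for k, v in data["bands"].items()}
    return RunConfig(**data)


def _ordered_stages(requested) -> list[str]:
    return [s for s in STAGES if s in set(requested)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order and write a report.

    Later stages load the outputs earlier stages wrote under
    ``config.out_dir``, so stage subsets can resume a previous run.
    Returns the report dict (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seeds": dict(config.seeds),
        "stages": {},
        "exclusions": {},
        "results": {},
    }
    study = None
    stages = _ordered_stages(config.stages)
    if not stages:
        raise ValueError("no known stage requested")
    study_path = out / "study.h5"

    def need_study():
        nonlocal study
        if study is None:
            if not study_path.exists():
                raise FileNotFoundError(
                    f"{study_path}: run the 'simulate' stage first"
                )
            study = snio.load_study(study_path)
        return study

    for stage in stages:
        t0 = time.perf_counter()
        log.info("stage %s starting", stage)
        try:
            if stage == "simulate":
                overrides = {}
                if config.beta_conn is not None:
                    overrides["beta_conn"] = config.beta_conn
                if config.beta_dist is not None:
                    overrides["beta_dist"] = config.beta_dist
                if config.noise_sd is not None:
                    overrides["noise_sd"] = config.noise_sd
                truth = make_ground_truth(
                    config.n_electrodes, seed=config.seeds["simulate"], **overrides
                )
                study = generate_study(
                    n_electrodes=config.n_electrodes,
                    n_sites=config.n_sites,
                    n_trials=config.n_trials,
                    n_baseline_periods=config.n_baseline_periods,
                    fs=config.fs,
                    seed=config.seeds["simulate"],
                    truth=truth,
                    spec=config.mt_spec,
                )
                snio.save_study(study, study_path)
                snio.write_layout(study.layout, out / "layout.tsv")
                report["stages"][stage] = {
                    "n_electrodes": study.layout.n_electrodes,
                    "n_sessions": len(study.sessions),
                }
            elif stage == "preprocess":
                st = need_study()
                masks = {}
                for i, sess in enumerate(st.sessions):
                    art = detect_artifact_channels(sess)
                    mask = apply_exclusions(st.layout, art, sess.stim_pair)
                    masks[i] = mask
                    report["exclusions"][f"session_{i}"] = {
                        lab: sorted(r) for lab, r in mask.reasons.items()
                    }
                np.save(out / "masks.npy", np.array(
                    [masks[i].included for i in range(len(st.sessions))]
                ))
                report["stages"][stage] = {
                    f"session_{i}": int(m.n_included) for i, m in masks.items()
                }
            elif stage == "connect":
                st = need_study()
                coh = coherence_network(
                    cut_windows(st.baseline, 1.0), config.mt_spec, fs=st.baseline.fs,
                    labels=list(st.layout.labels),
                )
                dist = distance_network(st.layout)
                snio.write_adjacency(coh, out / "coherence.tsv")
                snio.write_adjacency(dist, out / "distance.tsv")
                report["stages"][stage] = {"n_windows": coh.n_windows}
            elif stage == "evoked":
                st = need_study()
                rows = []
                for i, sess in enumerate(st.sessions):
                    for name, edges in config.bands.items():
                        if edges[1] >= st.baseline.fs / 2:
                            continue  # band above Nyquist for this rate
                        band = BANDS.get(name)
                        if band is None or band.edges != tuple(edges):
                            from .evoked import BandSpec

                            band = BandSpec(name, *edges)
                        con = session_power_contrast(sess, band, config.mt_spec)
                        for lab, t in zip(con.labels, con.t_stat):
                            rows.append((i, name, lab, t))
                import pandas as pd

                pd.DataFrame(
                    rows, columns=["session", "band", "electrode", "t"]
                ).to_csv(out / "power_contrasts.tsv", sep="\t", index=False)
                report["stages"][stage] = {"n_rows": len(rows)}
            elif stage == "nma":
                st = need_study()
                coh = snio.read_adjacency(out / "coherence.tsv")
                dist = snio.read_adjacency(out / "distance.tsv")
                import pandas as pd

                table = pd.read_csv(out / "power_contrasts.tsv", sep="\t")
                masks = np.load(out / "masks.npy")
                rng = np.random.default_rng(config.seeds["nma"])
                site_rows = []
                for i, sess in enumerate(st.sessions):
                    stim_label = "-".join(sess.stim_pair)
                    sub = table[(table.session == i) & (table.band == "theta")]
                    t = sub.set_index("electrode")["t"].reindex(st.layout.labels).to_numpy()
                    from .evoked import PowerContrast
                    from .recording import ChannelMask

                    included = masks[i]
                    reasons = {
                        lab: frozenset({"user"})
                        for lab, inc in zip(st.layout.labels, included)
                        if not inc
                    }
                    mask = ChannelMask(list(st.layout.labels), included, reasons)
                    con = PowerContrast(
                        t, st.sessions[i].n_trials, BANDS["theta"],
                        labels=list(st.layout.labels), mask=mask,
                    )
                    try:
                        res = compute_nma(
                            con, coh, dist, stim_label,
                            n_perm=config.n_perm,
                            seed=int(rng.integers(2**31 - 1)),
                            mode=config.perm_mode,
                        )
                    except TooFewElectrodesError as exc:
                        report["stages"].setdefault("nma_skipped", {})[
                            f"session_{i}"
                        ] = str(exc)
                        continue
                    site_rows.append(
                        {
                            "session": i,
                            "stim_site": stim_label,
                            "z": res.z,
                            "p": res.p_two_tailed,
                            "beta_conn": res.beta_conn,
                            "beta_dist": res.beta_dist,
                            "n_electrodes": res.n_electrodes,
                            "wm_distance_mm": float(
                                st.layout.wm_distance[st.layout.index(stim_label)]
                            ),
                            "in_wm": bool(
                                st.layout.in_wm[st.layout.index(stim_label)]
                            ),
                        }
                    )
                pd.DataFrame(site_rows).to_csv(out / "nma_sites.tsv", sep="\t", index=False)
                report["stages"][stage] = {"n_sites": len(site_rows)}
            elif stage == "group":
                import pandas as pd

                sites = pd.read_csv(out / "nma_sites.tsv", sep="\t")
                results: dict = {}
                if len(sites) >= 2 and sites["z"].std(ddof=1) > 0:
                    g = group_onesample_test(sites["z"].to_numpy(), "nma_vs_zero")
                    results["nma_vs_zero"] = {
                        "t": g.statistic, "p": g.p, "n": g.n,
                    }
                try:
                    cats = classify_wm(
                        sites["wm_distance_mm"].to_numpy(),
                        sites["in_wm"].to_numpy(bool),
                        direction=config.wm_direction,
                    )
                    trend = wm_trend_permutation_test(
                        sites["z"].to_numpy(), cats,
                        n_perm=config.n_perm, seed=config.seeds["group"],
                    )
                    results["wm_trend"] = {
                        "min_t": trend.statistic, "p": trend.p, "n": trend.n,
                    }
                except ValueError as exc:
                    results["wm_trend"] = {"skipped": str(exc)}
                sig = sites[sites["p"] < config.alpha]
                results["directional_counts"] = {
                    "n_negative": int((sig["z"] < 0).sum()),
                    "n_positive": int((sig["z"] > 0).sum()),
                    "n_sites": int(len(sites)),
                }
                report["results"].update(results)
                report["stages"][stage] = {"n_sites": int(len(sites))}
            dt = time.perf_counter() - t0
            report["stages"].setdefault(stage, {})
            log.info("stage %s done in %.2f s", stage, dt)
            report.setdefault("durations_s", {})[stage] = round(dt, 3)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    hashable = {
        k: report[k] for k in ("config_hash", "seeds", "stages", "exclusions", "results")
    }
    report["results_hash"] = hashlib.sha256(
        json.dumps(hashable, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
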