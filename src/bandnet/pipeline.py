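"""End-to-end orchestration: simulate → preprocess → connectivity → graph → stats.

A :class:`PipelineConfig` (built in code or parsed from YAML) describes either
a synthetic cohort or a directory of recorded subjects, the band list, and the
two significance levels.  :func:`run` executes the whole chain
deterministically under the master seed and writes tidy CSV tables plus a JSON
manifest (config hash, seed, package versions) sufficient to re-run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fc import build_network, pairwise_correlation, regional_edge_count
from .graph import compute_all
from .preprocess import bandpass, notch_filter, select_window
from .signals import DEFAULT_BANDS, BandDefinition, SignalSet, load_signalset
from .stats import SCORE_FIELDS, compare_regional_counts, compare_samples, correlate
from .synth import (
    CohortSpec,
    GroupSpec,
    block_coupling,
    default_cohort_spec,
    generate_cohort,
    generate_scores,
)

__all__ = ["PipelineConfig", "RunReport", "run", "validate_inputs", "load_config"]

log = logging.getLogger(__name__)

NETWORK_METRICS = ("DA", "SA", "LA", "CA")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    Exactly one of ``cohort`` (synthetic spec) or ``input_paths`` (saved
    SignalSet containers) must be given.  ``scores_path`` may point to a
    cognitive-score CSV; for synthetic cohorts scores are generated when it is
    absent.
    """

    cohort: CohortSpec | None = None
    input_paths: list[str] = field(default_factory=list)
    scores_path: str | None = None
    bands: Sequence[BandDefinition] = DEFAULT_BANDS
    notch_hz: float | None = 50.0
    window_start: float = 0.0
    window_length: float | None = None  # None: the full recording
    alpha_fc: float = 0.05
    alpha_stats: float = 0.05
    out_dir: str = "bandnet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort is None) == (not self.input_paths):
            # exactly one source: either a cohort spec or input paths
            if self.cohort is None:
                raise ValueError("config needs either 'cohort' or 'input_paths'")
            raise ValueError("config cannot have both 'cohort' and 'input_paths'")
        for p in self.input_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input_paths: {p} does not exist")
        if self.scores_path is not None and not Path(self.scores_path).exists():
            raise FileNotFoundError(f"scores_path: {self.scores_path} does not exist")
        if not (0 < self.alpha_fc < 1 and 0 < self.alpha_stats < 1):
            raise ValueError("alpha_fc and alpha_stats must be in (0, 1)")


@dataclass
class RunReport:
    """Tables and provenance of one pipeline run."""

    metrics: pd.DataFrame  # subject_id, group, band, metric, value
    node_metrics: pd.DataFrame
    regional_counts: pd.DataFrame
    group_tests: pd.DataFrame
    regional_tests: pd.DataFrame
    correlations: pd.DataFrame
    scores: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# config parsing (YAML)
# ---------------------------------------------------------------------------

def _parse_bands(node) -> tuple[BandDefinition, ...]:
    if node in (None, "default"):
        return DEFAULT_BANDS
    try:
        return tuple(
            BandDefinition(b["name"], float(b["low"]), float(b["high"])) for b in node
        )
    except (KeyError, TypeError) as e:
        raise ValueError(f"config error at bands: {e}") from e


def _parse_coupling(node, n_channels: int, where: str) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for band_name, val in (node or {}).items():
        if isinstance(val, dict):
            out[band_name] = block_coupling(
                n_channels,
                float(val.get("within", 0.0)),
                float(val.get("cross", 0.0)),
            )
        else:
            out[band_name] = np.asarray(val, dtype=float)
    return out


def _parse_cohort(node, seed: int) -> CohortSpec:
    if node == "default":
        return default_cohort_spec(seed=seed)
    if not isinstance(node, dict):
        raise ValueError("config error at cohort: expected 'default' or a mapping")
    if node.get("profile") == "default":
        return default_cohort_spec(
            seed=seed,
            n_subjects=int(node.get("n_subjects", 15)),
            n_channels=int(node.get("n_channels", 30)),
            sampling_rate=float(node.get("sampling_rate", 1000.0)),
            duration=float(node.get("duration", 30.0)),
        )
    n_channels = int(node.get("n_channels", 30))
    groups = []
    for g in node.get("groups", []):
        try:
            groups.append(
                GroupSpec(
                    name=g["name"],
                    n_subjects=int(g.get("n_subjects", 15)),
                    coupling=_parse_coupling(
                        g.get("coupling"), n_channels, f"groups/{g['name']}"
                    ),
                    spike_rate=float(g.get("spike_rate", 0.0)),
                    spike_amplitude=float(g.get("spike_amplitude", 8.0)),
                    noise_sd=float(g.get("noise_sd", 0.1)),
                )
            )
        except KeyError as e:
            raise ValueError(f"config error at cohort/groups: missing {e}") from e
    return CohortSpec(
        groups=groups,
        sampling_rate=float(node.get("sampling_rate", 1000.0)),
        duration=float(node.get("duration", 30.0)),
        n_channels=n_channels,
        seed=seed,
        bands=_parse_bands(node.get("bands")),
    )


def load_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Parse a YAML pipeline config; `seed` overrides the file's seed."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config error at <root>: expected a mapping")
    use_seed = int(seed if seed is not None else raw.get("seed", 0))
    cohort = None
    if "cohort" in raw:
        cohort = _parse_cohort(raw["cohort"], use_seed)
    return PipelineConfig(
        cohort=cohort,
        input_paths=list(raw.get("input_paths", [])),
        scores_path=raw.get("scores_path"),
        bands=_parse_bands(raw.get("bands")),
        notch_hz=raw.get("notch_hz", 50.0),
        window_start=float(raw.get("window_start", 0.0)),
        window_length=raw.get("window_length"),
        alpha_fc=float(raw.get("alpha_fc", 0.05)),
        alpha_stats=float(raw.get("alpha_stats", 0.05)),
        out_dir=str(raw.get("out_dir", "bandnet_out")),
        seed=use_seed,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(
    paths: Sequence[str | Path],
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> list[str]:
    """Read-only sanity report on saved SignalSet containers.

    Checks matrix/metadata consistency, NaN/Inf, and per-band sampling-rate
    adequacy; returns a list of problem strings (empty = all good).
    """
    problems: list[str] = []
    for p in paths:
        p = Path(p)
        try:
            s = load_signalset(p)
        except Exception as e:  # malformed container: report, keep going
            problems.append(f"{p}: unreadable ({e})")
            continue
        for b in bands:
            if b.high >= s.sampling_rate / 2:
                problems.append(
                    f"{p}: band {b.name!r} top edge {b.high} Hz reaches Nyquist "
                    f"at {s.sampling_rate} Hz sampling"
                )
    return problems


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _config_digest(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    blob = json.dumps(asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _analyze_subject(
    s: SignalSet, config: PipelineConfig
) -> tuple[list[dict], list[dict], list[dict]]:
    if config.window_length is not None:
        s = select_window(s, config.window_start, config.window_length)
    if config.notch_hz:
        s = notch_filter(s, config.notch_hz)
    metric_rows, node_rows, regional_rows = [], [], []
    for band in config.bands:
        filtered = bandpass(s, band)
        conn = pairwise_correlation(filtered, band=band)
        net = build_network(conn, alpha=config.alpha_fc)
        counts = regional_edge_count(net, s.channels)
        gm = compute_all(net)
        for m in NETWORK_METRICS:
            metric_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "band": band.name,
                    "metric": m,
                    "value": gm.as_dict()[m],
                }
            )
        for i, ch in enumerate(s.channels):
            node_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "band": band.name,
                    "node": ch.label,
                    "degree": gm.degree[i],
                    "strength": gm.strength[i],
                    "clustering": gm.clustering[i],
                }
            )
        regional_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "band": band.name,
                "n_edges": net.n_edges,
                **counts,
            }
        )
    return metric_rows, node_rows, regional_rows


def run(config: PipelineConfig, write: bool = True) -> RunReport:
    """Execute the full analysis chain; deterministic given the seed.

    A failure while processing one subject aborts the run with an error naming
    that subject.
    """
    t0 = time.perf_counter()
    if config.cohort is not None:
        log.info("generating synthetic cohort (seed=%d)", config.seed)
        subjects, _truth = generate_cohort(config.cohort)
    else:
        subjects = [load_signalset(p) for p in config.input_paths]

    # cognitive scores: from file, or synthesized for synthetic cohorts
    if config.scores_path is not None:
        scores = pd.read_csv(config.scores_path)
    elif config.cohort is not None:
        ss = np.random.SeedSequence((config.seed, 0xC0D))
        parts = []
        for child, g in zip(ss.spawn(len(config.cohort.groups)), config.cohort.groups):
            sids = [s.subject_id for s in subjects if s.group == g.name]
            parts.append(generate_scores(g.name, sids, child))
        scores = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=["subject_id", "group", *SCORE_FIELDS])
        )
    else:
        scores = pd.DataFrame(columns=["subject_id", "group", *SCORE_FIELDS])

    metric_rows: list[dict] = []
    node_rows: list[dict] = []
    regional_rows: list[dict] = []
    for s in subjects:
        try:
            m, n, r = _analyze_subject(s, config)
        except Exception as e:
            raise RuntimeError(
                f"analysis failed for subject {s.subject_id!r}: {e}"
            ) from e
        metric_rows += m
        node_rows += n
        regional_rows += r
        log.info("subject %s done", s.subject_id)

    metrics = pd.DataFrame(metric_rows)
    node_metrics = pd.DataFrame(node_rows)
    regional = pd.DataFrame(regional_rows)

    groups = sorted(metrics["group"].unique()) if len(metrics) else []
    band_names = [b.name for b in config.bands]

    # group comparisons per band × metric
    test_rows: list[dict] = []
    if len(groups) >= 2:
        for band in band_names:
            for metric in NETWORK_METRICS:
                sub = metrics[(metrics["band"] == band) & (metrics["metric"] == metric)]
                samples = {
                    g: grp["value"].to_numpy()
                    for g, grp in sub.groupby("group", sort=True)
                }
                if any(v.size < 3 for v in samples.values()):
                    continue
                res = compare_samples(
                    samples, alpha=config.alpha_stats, metric=metric, band=band
                )
                for pw in res.pairwise:
                    test_rows.append(
                        {
                            "band": band,
                            "metric": metric,
                            "test_used": res.test_used,
                            "omnibus_statistic": res.omnibus_statistic,
                            "omnibus_p": res.omnibus_p,
                            "group_a": pw.group_a,
                            "group_b": pw.group_b,
                            "statistic": pw.statistic,
                            "p_raw": pw.p_raw,
                            "p_corrected": pw.p_corrected,
                            "alpha_corrected": res.alpha_corrected,
                            "significant": pw.significant,
                        }
                    )
    group_tests = pd.DataFrame(test_rows)

    # regional contingency tests (anterior-posterior share) per band, group pairs
    reg_rows: list[dict] = []
    if len(groups) >= 2:
        for band in band_names:
            sub = regional[regional["band"] == band]
            agg = {
                g: {
                    k: int(grp[k].sum())
                    for k in (
                        "anterior-anterior",
                        "anterior-posterior",
                        "posterior-posterior",
                    )
                }
                for g, grp in sub.groupby("group", sort=True)
            }
            for i, a in enumerate(groups):
                for b in groups[i + 1 :]:
                    odds, p = compare_regional_counts(agg[a], agg[b])
                    reg_rows.append(
                        {
                            "band": band,
                            "group_a": a,
                            "group_b": b,
                            "ap_edges_a": agg[a]["anterior-posterior"],
                            "ap_edges_b": agg[b]["anterior-posterior"],
                            "odds_ratio": odds,
                            "p": p,
                        }
                    )
    regional_tests = pd.DataFrame(reg_rows)

    # metric–score correlations per group × band × metric × score
    corr_rows: list[dict] = []
    if len(scores) and len(metrics):
        wide = metrics.pivot_table(
            index=["subject_id", "group", "band"], columns="metric", values="value"
        ).reset_index()
        merged = wide.merge(scores, on=["subject_id", "group"], how="inner")
        for (g, band), sub in merged.groupby(["group", "band"], sort=True):
            for metric in NETWORK_METRICS:
                for score in SCORE_FIELDS:
                    if score not in sub.columns or len(sub) < 5:
                        continue
                    res = correlate(sub[metric], sub[score])
                    corr_rows.append(
                        {
                            "group": g,
                            "band": band,
                            "metric": metric,
                            "score": score,
                            "R": res.R,
                            "p": res.p,
                            "method": res.method,
                            "n": res.n,
                        }
                    )
    correlations = pd.DataFrame(corr_rows)

    manifest = {
        "package": "bandnet",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_digest(config),
        "n_subjects": len(subjects),
        "bands": [[b.name, b.low, b.high] for b in config.bands],
        "alpha_fc": config.alpha_fc,
        "alpha_stats": config.alpha_stats,
        "versions": {
            "numpy": np.__version__,
            "scipy": __import__("scipy").__version__,
            "pandas": pd.__version__,
        },
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }

    report = RunReport(
        metrics=metrics,
        node_metrics=node_metrics,
        regional_counts=regional,
        group_tests=group_tests,
        regional_tests=regional_tests,
        correlations=correlations,
        scores=scores,
        manifest=manifest,
    )
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        node_metrics.to_csv(out / "node_metrics.csv", index=False)
        regional.to_csv(out / "regional_counts.csv", index=False)
        group_tests.to_csv(out / "group_tests.csv", index=False)
        regional_tests.to_csv(out / "regional_tests.csv", index=False)
        correlations.to_csv(out / "correlations.csv", index=False)
        scores.to_csv(out / "scores.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.info("report written to %s", out)
    return report
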