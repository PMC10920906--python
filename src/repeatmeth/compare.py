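"""Per-repeat statistics and end-to-end pipeline orchestration.

The unit of statistical analysis is the biological repeat: every readout is
first averaged within a repeat, and for each repeat the two condition means
are normalized to their own average, so that within every repeat the two
normalized values average to exactly 1.  Comparisons use classical two-tailed
t tests (paired on differences, or the pooled-variance unpaired form; a
Welch option exists for unequal variances) and one-way ANOVA for three or
more groups.  Raw p-values are reported with the test name — no
multiple-testing correction is applied — and mapped to significance stars
(*p<0.05, **p<0.01, ***p<0.001, ****p<0.0001).

The statistics are computed from the textbook closed forms (scipy supplies
only the t/F distribution functions), so independent implementations can
serve as oracles in the test suite.

:func:`run_pipeline` chains the synthetic generators through the
quantification stages into a JSON + CSV report that is byte-identical for a
fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _dist

from . import _config

__all__ = [
    "TestResult",
    "two_condition_normalize",
    "paired_t",
    "unpaired_t",
    "one_way_anova",
    "significance_stars",
    "run_pipeline",
    "PIPELINE_EXPERIMENTS",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return "n/a"
    for threshold, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < threshold:
            return mark
    return "ns"


def two_condition_normalize(repeat_means_a, repeat_means_b) -> tuple[np.ndarray, np.ndarray]:
    """Normalize each repeat's pair of condition means to their own average.

    For repeat i with raw means (A_i, B_i), m_i = (A_i + B_i)/2 and the
    normalized pair is (A_i/m_i, B_i/m_i), whose mean is 1 by construction.
    """
    a = np.asarray(repeat_means_a, dtype=float)
    b = np.asarray(repeat_means_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expect two equal-length 1-D lists of per-repeat means")
    m = (a + b) / 2.0
    if np.any(~np.isfinite(m)) or np.any(m <= 0):
        raise ValueError("per-repeat pair means must be finite and > 0")
    return a / m, b / m


def paired_t(values_a, values_b) -> TestResult:
    """Two-tailed paired Student t test on per-repeat differences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test requires equal-length 1-D samples")
    n = a.size
    if n < 2:
        raise ValueError("paired t test needs at least 2 repeats")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult("paired_t", 0.0, 1.0, n, degenerate=True)
        return TestResult("paired_t", math.copysign(math.inf, d.mean()), 0.0, n, degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * _dist.t.sf(abs(t), df=n - 1)
    return TestResult("paired_t", float(t), float(p), n)


def unpaired_t(values_a, values_b, welch: bool = False) -> TestResult:
    """Two-tailed unpaired t test (pooled-variance Student form by default)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValueError("unpaired t test needs two samples of at least 2 values each")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return _degenerate_t("welch_t", diff, na + nb)
        t = diff / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        name = "welch_t"
    else:
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if pooled == 0:
            return _degenerate_t("unpaired_t", diff, na + nb)
        t = diff / math.sqrt(pooled * (1 / na + 1 / nb))
        df = na + nb - 2
        name = "unpaired_t"
    p = 2.0 * _dist.t.sf(abs(t), df=df)
    return TestResult(name, float(t), float(p), na + nb)


def _degenerate_t(name: str, diff: float, n: int) -> TestResult:
    if diff == 0:
        return TestResult(name, 0.0, 1.0, n, degenerate=True)
    return TestResult(name, math.copysign(math.inf, diff), 0.0, n, degenerate=True)


def one_way_anova(groups) -> TestResult:
    """Classical one-way ANOVA: between/within F with the F distribution."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    if any(g.ndim != 1 or g.size < 2 for g in arrays):
        raise ValueError("every group needs at least 2 values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    n_total = all_values.size
    k = len(arrays)
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ss_within == 0:
        if ss_between == 0:
            return TestResult("anova", 0.0, 1.0, n_total, degenerate=True)
        return TestResult("anova", math.inf, 0.0, n_total, degenerate=True)
    f = (ss_between / (k - 1)) / (ss_within / (n_total - k))
    p = _dist.f.sf(f, k - 1, n_total - k)
    return TestResult("anova", float(f), float(p), n_total)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


def _derive_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _experiment_msre(preset: str, seed: int, n_biological: int) -> dict:
    """Simulated MSRE-qPCR plate -> per-repeat relative methylation."""
    from . import qpcr, synthgen

    cfg = synthgen.qpcr_preset(preset, seed=seed, n_biological=n_biological)
    plate = synthgen.simulate_qpcr_plate(cfg)
    cond_a, cond_b = (c[0] for c in cfg.conditions)
    est = qpcr.msre_relative_methylation(plate, efficiency=cfg.efficiency)
    wide = est.pivot(index="biological_repeat", columns="condition", values="relative_methylation")
    return {
        "measure_name": "relative_methylation",
        "conditions": (cond_a, cond_b),
        "raw_a": wide[cond_a].to_numpy(),
        "raw_b": wide[cond_b].to_numpy(),
        "test": "unpaired_t",
        "stage_tables": {"ct_table": plate, "methylation": est},
        "exclusions": {},
    }


def _experiment_spot_images(
    preset_a: str, preset_b: str, seed: int, n_repeats: int, n_nuclei: int
) -> dict:
    """Paired synthetic image fields -> per-repeat mean corrected spot signal."""
    from . import imagequant, synthgen

    seeds = _derive_seeds(seed, 2 * n_repeats)
    raw = {preset_a: [], preset_b: []}
    records = []
    skipped = 0
    for r in range(n_repeats):
        for preset, s in ((preset_a, seeds[2 * r]), (preset_b, seeds[2 * r + 1])):
            cfg = synthgen.SceneConfig(seed=s, n_nuclei=n_nuclei)
            stack, _truth = synthgen.simulate_nuclei_stack(cfg, preset)
            dna = imagequant.max_project(stack, "dna")
            reporter = imagequant.max_project(stack, "reporter")
            seg = imagequant.segment_nuclei(dna)
            spots = imagequant.quantify_spots(seg.label_image, reporter)
            usable = spots["corrected_signal"].dropna()
            skipped += int(spots["corrected_signal"].isna().sum())
            raw[preset].append(float(usable.mean()))
            spots.insert(0, "condition", preset)
            spots.insert(1, "biological_repeat", r + 1)
            records.append(spots)
    return {
        "measure_name": "corrected_spot_signal",
        "conditions": (preset_a, preset_b),
        "raw_a": np.array(raw[preset_a]),
        "raw_b": np.array(raw[preset_b]),
        "test": "paired_t",
        "stage_tables": {"spot_records": pd.concat(records, ignore_index=True)},
        "exclusions": {"nuclei_without_spot_mask": skipped},
    }


def _experiment_nuclear_intensity(
    preset_a: str, preset_b: str, seed: int, n_repeats: int, n_nuclei: int
) -> dict:
    """Paired synthetic fields -> per-repeat mean nuclear channel intensity."""
    from . import imagequant, synthgen

    seeds = _derive_seeds(seed, 2 * n_repeats)
    raw = {preset_a: [], preset_b: []}
    for r in range(n_repeats):
        for preset, s in ((preset_a, seeds[2 * r]), (preset_b, seeds[2 * r + 1])):
            cfg = synthgen.SceneConfig(seed=s, n_nuclei=n_nuclei)
            stack, _truth = synthgen.simulate_nuclei_stack(cfg, preset)
            dna = imagequant.max_project(stack, "dna")
            stain = imagequant.mean_project(stack, "reporter")
            seg = imagequant.segment_nuclei(dna)
            table = imagequant.mean_nuclear_intensity(seg.label_image, stain)
            raw[preset].append(float(table["mean_intensity"].mean()))
    return {
        "measure_name": "mean_nuclear_intensity",
        "conditions": (preset_a, preset_b),
        "raw_a": np.array(raw[preset_a]),
        "raw_b": np.array(raw[preset_b]),
        "test": "paired_t",
        "stage_tables": {},
        "exclusions": {},
    }


def _experiment_msd(seed: int, n_repeats: int, d_a: float, d_b: float) -> dict:
    """Simulated spot motion -> per-repeat mean MSD at the 1 s lag."""
    from . import motility, synthgen

    seeds = _derive_seeds(seed, 2 * n_repeats)
    raw_a, raw_b = [], []
    excluded = 0
    for r in range(n_repeats):
        for d, sink, s in ((d_a, raw_a, seeds[2 * r]), (d_b, raw_b, seeds[2 * r + 1])):
            cfg = synthgen.MotionConfig(
                n_trajectories=60, n_frames=50, diffusion_coefficient=d, seed=s
            )
            trajectories, _truth = synthgen.simulate_trajectories(cfg)
            profiles = motility.compute_msd(trajectories, max_lag=1.0, mode="per_trajectory")
            summary = motility.mobility_summary(profiles, lag_target=1.0)
            kept = summary.scores.loc[~summary.scores["outlier"], "msd_at_lag"]
            excluded += summary.n_excluded_short + int(summary.scores["outlier"].sum())
            sink.append(float(kept.mean()))
    return {
        "measure_name": "msd_at_1s",
        "conditions": ("sparse", "dense"),
        "raw_a": np.array(raw_a),
        "raw_b": np.array(raw_b),
        "test": "paired_t",
        "stage_tables": {},
        "exclusions": {"trajectories_excluded": excluded},
    }


#: Named end-to-end experiments understood by :func:`run_pipeline`.
PIPELINE_EXPERIMENTS = {
    "aza_vs_mock": lambda seed, cfg: _experiment_msre(
        "mcf10a_aza", seed, cfg.get("n_biological", 3)
    ),
    "mcf7_aza_vs_mock": lambda seed, cfg: _experiment_msre(
        "mcf7_aza", seed, cfg.get("n_biological", 3)
    ),
    "sparse_vs_dense_msre": lambda seed, cfg: _experiment_msre(
        "mcf10a_density", seed, cfg.get("n_biological", 3)
    ),
    "sparse_vs_dense": lambda seed, cfg: _experiment_spot_images(
        "sparse", "dense", seed, cfg.get("n_repeats", 4), cfg.get("n_nuclei", 8)
    ),
    "bobcat_vs_mock": lambda seed, cfg: _experiment_nuclear_intensity(
        "bobcat_treated", "mock", seed, cfg.get("n_repeats", 3), cfg.get("n_nuclei", 8)
    ),
    "sparse_vs_dense_msd": lambda seed, cfg: _experiment_msd(
        seed, cfg.get("n_repeats", 3), cfg.get("d_sparse", 0.01), cfg.get("d_dense", 0.005)
    ),
}


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run a named experiment end to end and write its report.

    ``config`` is a flat typed key-value mapping (or path to a ``key = value``
    file) with required keys ``experiment`` and ``seed``; optional keys
    override experiment sizes (``n_biological``, ``n_repeats``, ``n_nuclei``)
    and ``plots = true`` adds a per-repeat dot plot.  Outputs under
    ``outdir`` (or config key ``outdir``): ``summary.json``, per-stage CSVs,
    and the plot.  Deterministic given the seed: running twice produces
    byte-identical JSON.
    """
    if not isinstance(config, dict):
        config = _config.parse_kv(config)
    for key in ("experiment", "seed"):
        if key not in config:
            raise ValueError(f"pipeline config missing required key {key!r}")
    experiment = config["experiment"]
    if experiment not in PIPELINE_EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {experiment!r}; known: {sorted(PIPELINE_EXPERIMENTS)}"
        )
    seed = int(config["seed"])
    result = PIPELINE_EXPERIMENTS[experiment](seed, config)

    norm_a, norm_b = two_condition_normalize(result["raw_a"], result["raw_b"])
    if result["test"] == "paired_t":
        test = paired_t(norm_a, norm_b)
    else:
        test = unpaired_t(norm_a, norm_b)

    cond_a, cond_b = result["conditions"]
    config_text = _config.format_kv(config)
    summary = {
        "experiment": experiment,
        "measure_name": result["measure_name"],
        "conditions": [cond_a, cond_b],
        "n_repeats": len(norm_a),
        "per_repeat": {
            "raw": {cond_a: list(result["raw_a"]), cond_b: list(result["raw_b"])},
            "normalized": {cond_a: list(norm_a), cond_b: list(norm_b)},
        },
        "test": {**asdict(test), "stars": test.stars},
        "exclusions": result["exclusions"],
        "provenance": {
            "seed": seed,
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
            "package_version": _package_version(),
        },
    }

    out = Path(outdir) if outdir is not None else Path(config.get("outdir") or ".")
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    per_repeat = pd.DataFrame(
        {
            "biological_repeat": np.arange(1, len(norm_a) + 1),
            f"raw_{cond_a}": result["raw_a"],
            f"raw_{cond_b}": result["raw_b"],
            f"normalized_{cond_a}": norm_a,
            f"normalized_{cond_b}": norm_b,
        }
    )
    per_repeat.to_csv(out / "per_repeat.csv", index=False)
    for name, table in result["stage_tables"].items():
        table.to_csv(out / f"{name}.csv", index=False)
    if config.get("plots"):
        _dot_plot(per_repeat, cond_a, cond_b, result["measure_name"], out / "dotplot.png")
    return summary


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("repeatmeth")
    except PackageNotFoundError:
        return "unknown"


def _dot_plot(per_repeat: pd.DataFrame, cond_a: str, cond_b: str, measure: str, path: Path) -> None:
    """Mean ± SD bars with per-repeat dots, one x position per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 4))
    for x, cond in ((0, cond_a), (1, cond_b)):
        vals = per_repeat[f"normalized_{cond}"].to_numpy()
        ax.scatter(np.full(vals.shape, x), vals, zorder=3)
        ax.errorbar(
            [x], [vals.mean()], yerr=[vals.std(ddof=1)] if len(vals) > 1 else None,
            fmt="_", color="black", capsize=6, markersize=24, zorder=2,
        )
    ax.set_xticks([0, 1], [cond_a, cond_b])
    ax.set_xlim(-0.5, 1.5)
    ax.set_ylabel(f"normalized {measure}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
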