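"""Simulation benchmarks: recover the generator presets through the pipeline.

Each benchmark runs a documented condition preset through the full
quantification stack and reports the recovered effect size on the scale a
figure legend would print (percent of mock, percent increase).  They are the
package's self-checks that the analysis stages invert the generative model.
"""

from __future__ import annotations

import numpy as np

from . import imagequant, qpcr, synthgen

__all__ = [
    "aza_recovery_percent",
    "bobcat_intensity_increase_percent",
]


def aza_recovery_percent(
    preset: str = "mcf10a_aza",
    seed: int = 0,
    n_plates: int = 40,
    n_biological: int = 3,
    technical_sd: float = 0.2,
) -> dict:
    """Treated-vs-mock relative methylation recovered from simulated plates.

    Simulates ``n_plates`` independent MSRE-qPCR plates under the given drug
    preset (each plate with ``n_biological`` repeats and the stated technical
    noise), runs :func:`repeatmeth.qpcr.msre_relative_methylation` with the
    mock condition as reference, and averages the per-repeat treated
    percentage over all plates and repeats.  The multi-plate average tightens
    the Monte-Carlo error of the estimate without changing the per-plate
    design.

    Returns ``{"percent_of_mock": float, "n": repeats used}``.
    """
    rng = np.random.default_rng(seed)
    plate_seeds = rng.integers(0, 2**31 - 1, size=n_plates)
    treated_name = next(
        name for name, _, _ in synthgen.QPCR_PRESETS[preset] if name != "mock"
    )
    percents = []
    for plate_seed in plate_seeds:
        cfg = synthgen.qpcr_preset(
            preset,
            seed=int(plate_seed),
            n_biological=n_biological,
            technical_sd=technical_sd,
            include_expression=False,
        )
        plate = synthgen.simulate_qpcr_plate(cfg)
        est = qpcr.msre_relative_methylation(
            plate, efficiency=cfg.efficiency, reference_condition="mock"
        )
        treated = est.loc[est["condition"] == treated_name, "percent_of_reference"]
        percents.extend(treated.tolist())
    return {"percent_of_mock": float(np.mean(percents)), "n": len(percents)}


def bobcat_intensity_increase_percent(
    seed: int = 0,
    n_nuclei_per_condition: int = 50,
    nuclei_per_field: int = 10,
) -> dict:
    """Percent increase in mean nuclear 5mC-stain intensity, treated vs mock.

    Generates paired mock / TET-inhibited fields (``nuclei_per_field`` nuclei
    each, default noise) until ``n_nuclei_per_condition`` nuclei per
    condition exist, segments the max-projected DNA channel, measures
    per-nucleus mean intensity on the mean-projected stain channel (the
    linear projection, so multiplicative effects survive), and reports
    ``100 * (treated/mock − 1)`` on the pooled per-nucleus means.

    Returns ``{"percent_increase": float, "n": nuclei per condition}``.
    """
    n_fields = int(np.ceil(n_nuclei_per_condition / nuclei_per_field))
    rng = np.random.default_rng(seed)
    field_seeds = rng.integers(0, 2**31 - 1, size=2 * n_fields)
    per_nucleus = {"mock": [], "bobcat_treated": []}
    for f in range(n_fields):
        for preset, s in (
            ("mock", field_seeds[2 * f]),
            ("bobcat_treated", field_seeds[2 * f + 1]),
        ):
            cfg = synthgen.SceneConfig(seed=int(s), n_nuclei=nuclei_per_field)
            stack, _truth = synthgen.simulate_nuclei_stack(cfg, preset)
            dna = imagequant.max_project(stack, "dna")
            stain = imagequant.mean_project(stack, "reporter")
            seg = imagequant.segment_nuclei(dna)
            table = imagequant.mean_nuclear_intensity(seg.label_image, stain)
            per_nucleus[preset].extend(table["mean_intensity"].tolist())
    n = min(len(per_nucleus["mock"]), len(per_nucleus["bobcat_treated"]), n_nuclei_per_condition)
    mock = float(np.mean(per_nucleus["mock"][:n]))
    treated = float(np.mean(per_nucleus["bobcat_treated"][:n]))
    return {"percent_increase": 100.0 * (treated / mock - 1.0), "n": n}
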