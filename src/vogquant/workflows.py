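"""Reproducible study-condition workflows.

Each function regenerates a full synthetic experiment under the conditions
the analysis was validated against, runs the complete pipeline on it, and
returns the headline quantity: labeled-IN colocalization with mature
virions, either-or-both trans-labeling frequency, flow-cytometry infectivity
recovery, and the Gag vs Gag-Pol per-particle intensity ratio.

Problem sizes (number of 512x512 fields, events per flow table) are chosen
so each workflow runs in minutes on one CPU; every random draw derives from
the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coloc import colocalize, intensity_summary
from .config import RunConfig
from .detect import measure_at
from .infectivity import gate_singlets, percent_positive
from .optics import max_project
from .pipeline import deconvolve_and_project, detect_channels
from .synth import ConstructModel, FieldParams, simulate_field, simulate_flow_events

__all__ = [
    "measure_colocalization_recovery",
    "measure_labeling_frequency",
    "measure_infectivity_recovery",
    "measure_stoichiometry_ratio",
]


def _field_seeds(seed: int, n: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def measure_colocalization_recovery(
    seed: int = 0,
    n_fields: int = 16,
    dual_label_fraction: float = 0.85,
    threshold_um: float = 0.500,
) -> dict:
    """Colocalized fraction of mature virions with the tagged-IN channel.

    Simulates ``n_fields`` default virus-on-glass fields (~1000 particles in
    total at 0.02 particles/um^2) where a gag-anchored green construct labels
    each particle with probability ``dual_label_fraction``; runs deconvolve
    -> project -> detect -> pair-to-reference at the 0.500 um rule and pools
    pairs over fields.
    """
    cfg = RunConfig()
    construct = ConstructModel(name="optiGag-IN", channel="green")
    n_ref = n_paired = n_true = 0
    for s in _field_seeds(seed, n_fields, tag=1):
        field, truth = simulate_field(
            FieldParams(seed=s), [construct], dual_label_fraction=dual_label_fraction
        )
        projected = deconvolve_and_project(field, cfg)
        tables = detect_channels(projected, field.pixel_size_um, cfg)
        result = colocalize(tables["farred"], tables["green"], threshold_um)
        n_ref += result.n_reference
        n_paired += result.n_paired
        n_true += len(truth)
    return {
        "fraction": n_paired / n_ref,
        "percent": 100.0 * n_paired / n_ref,
        "n_reference": n_ref,
        "n_true_particles": n_true,
    }


def measure_labeling_frequency(
    seed: int = 0,
    n_fields: int = 37,
    incorporation_prob: float = 0.7,
    threshold_um: float = 0.500,
) -> dict:
    """Fraction of mature virions detected in at least one fluorophore channel.

    Two trans-supplied constructs (green and red, both gag-anchored) each
    label a particle independently with ``incorporation_prob``; the workflow
    counts reference-channel detections with a paired green OR red detection
    at the 0.500 um rule.  The default 37 fields give >= 2000 mature
    particles in total.
    """
    cfg = RunConfig()
    constructs = [
        ConstructModel(name="optiGag-green", channel="green", incorporation_prob=incorporation_prob),
        ConstructModel(name="optiGag-red", channel="red", incorporation_prob=incorporation_prob),
    ]
    n_ref = n_any = n_mature = 0
    for s in _field_seeds(seed, n_fields, tag=2):
        field, truth = simulate_field(FieldParams(seed=s), constructs)
        projected = deconvolve_and_project(field, cfg)
        tables = detect_channels(projected, field.pixel_size_um, cfg)
        paired_ids: set[int] = set()
        n_reference = 0
        for channel in ("green", "red"):
            result = colocalize(tables["farred"], tables[channel], threshold_um)
            paired_ids |= set(result.pairs.ref_id)
            n_reference = result.n_reference
        n_ref += n_reference
        n_any += len(paired_ids)
        n_mature += int(truth.mature.sum())
    return {
        "fraction": n_any / n_ref,
        "percent": 100.0 * n_any / n_ref,
        "n_reference": n_ref,
        "n_mature_simulated": n_mature,
    }


def measure_infectivity_recovery(
    seed: int = 0,
    n_events: int = 50_000,
    infected_fraction: float = 0.70,
    separation: float = 4.0,
    doublet_fraction: float = 0.05,
    gate_quantile: float = 0.999,
) -> dict:
    """Percent GFP-positive singlets for a labeled-IN infection condition.

    Generates the condition table and a matched non-infected control, gates
    singlets on both, anchors the GFP gate at the control quantile, and
    reports the recovered percent positive.
    """
    s1, s2 = _field_seeds(seed, 2, tag=3)
    events = simulate_flow_events(
        n_events, infected_fraction, separation, seed=s1,
        doublet_fraction=doublet_fraction, condition="labeled-IN",
    )
    control = simulate_flow_events(
        n_events, 0.0, separation, seed=s2,
        doublet_fraction=doublet_fraction, condition="negative",
    )
    gated = gate_singlets(events)
    gated_control = gate_singlets(control)
    result = percent_positive(gated, gated_control, quantile=gate_quantile)
    return {
        "percent": result.percent_positive,
        "n_singlets": result.n_singlets,
        "gate_value": result.gate_value,
    }


def measure_stoichiometry_ratio(seed: int = 0, n_fields: int = 3) -> dict:
    """Median per-particle intensity ratio of Gag- vs Pol-anchored labeling.

    Both preparations carry the label in the same (red) channel, mirroring a
    same-fluorophore construct comparison.  Particles are identified on the
    deconvolved mature-capsid reference channel, and the construct channel
    is measured by anchored mask photometry on its raw projection (annulus
    background, no per-pixel floor), which stays unbiased for the dim
    Pol-anchored particles near the detection floor.
    """
    cfg = RunConfig()
    tables = {}
    counts = {}
    for tag, mode in ((4, "gag_anchored"), (5, "pol_anchored")):
        construct = ConstructModel(name=mode, channel="red", in_label_mode=mode)
        per_field = []
        for s in _field_seeds(seed, n_fields, tag=tag):
            field, _ = simulate_field(FieldParams(seed=s), [construct])
            projected = deconvolve_and_project(field, cfg)
            ref_table = detect_channels(
                {"farred": projected["farred"]}, field.pixel_size_um, cfg
            )["farred"]
            red_raw = max_project(field.channel("red"))
            per_field.append(
                measure_at(
                    red_raw,
                    ref_table.df[["y_px", "x_px"]].to_numpy(),
                    field.pixel_size_um,
                    channel="red",
                )
            )
        pooled = per_field[0]
        pooled.df = pd.concat([t.df for t in per_field], ignore_index=True)
        tables[mode] = pooled
        counts[mode] = len(pooled)
    summary, ratios = intensity_summary(tables, n_boot=500, seed=seed)
    row = ratios[
        (ratios.numerator == "gag_anchored") & (ratios.denominator == "pol_anchored")
    ].iloc[0]
    return {
        "ratio": float(row.median_ratio),
        "ci_low": float(row.ratio_ci_low),
        "ci_high": float(row.ratio_ci_high),
        "n_gag": counts["gag_anchored"],
        "n_pol": counts["pol_anchored"],
    }
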