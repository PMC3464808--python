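"""End-to-end demo pipeline: predict -> design -> simulated screen ->
growth / copy-number / stability reports.

Every stage writes a plain-text table into the output directory and all
randomness derives from the single top-level seed, so a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import burial, datasets, growth, library, qpcr, simulate, stability
from .io import write_fasta, write_table

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 0,
    "max_sites": 10,
    "strategy": "kstw",
    "threshold_avg": 0.90,
    "threshold_moment": 0.80,
    # growth stage: control vs mutant true rates (h^-1) at the assay temperature
    "mu_control": 0.42,
    "mu_mutant": 0.30,
    "growth_noise_sd": 0.01,
    # qPCR stage
    "eff_target": 1.008,
    "eff_ref": 0.971,
    "pcn_true": 8.0,
    "cq_noise_sd": 0.1,
    # stability stage
    "loss_prob_permissive": 0.05,
    "loss_prob_restrictive": 0.5,
    "plating_cv": 0.05,
}


def run_pipeline(config: dict | None = None, out_dir: str | Path = "pipeline_out") -> dict:
    """Run all stages on a synthetic stand-in replication protein.

    Returns a summary dict; artifacts land in ``out_dir``.  Unknown
    configuration keys are rejected.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg["seed"]).spawn(6)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    # -- stage 1: burial prediction on the stand-in CDS ------------------
    cds = datasets.synthetic_repb_like_cds(seed=child[0])
    protein = library.translate_cds(cds).rstrip("*")
    profile = burial.predict_profile(protein)
    regions = burial.find_buried_regions(
        profile, cfg["threshold_avg"], cfg["threshold_moment"]
    )
    write_table(out / "burial_profile.tsv", profile.to_frame())
    write_table(
        out / "buried_regions.tsv",
        pd.DataFrame(
            [
                {
                    "start": r.start, "end": r.end, "peak": r.peak,
                    "criterion": r.criterion, "peak_probability": r.peak_probability,
                }
                for r in regions
            ]
        ),
    )

    # -- stage 2: library design at the region peaks ---------------------
    usage = datasets.load_codon_usage()
    sites = []
    for r in regions[: cfg["max_sites"]]:
        wild = protein[r.peak - 1]
        subs = library.design_substitutions(
            wild, strategy=cfg["strategy"], seed=child[1] + r.peak
        )
        sites.append((r.peak, subs))
    lib = library.build_library(cds, sites, usage)
    write_fasta(out / "mutants.fasta", [(m.spec.name, m.cds) for m in lib.members])
    write_table(
        out / "library_manifest.tsv",
        pd.DataFrame(
            [
                {
                    "name": m.spec.name, "position": m.spec.position,
                    "old": m.spec.old_aa, "new": m.spec.new_aa,
                    "codon_old": m.spec.codon_old, "codon_new": m.spec.codon_new,
                }
                for m in lib.members
            ]
        ),
    )

    # -- stage 3: simulated two-temperature screen -----------------------
    rng = np.random.default_rng(child[2])
    calls = []
    for m in lib.members:
        draw = rng.random()
        if draw < 0.2:
            g48, g58 = "+", "-"      # temperature-sensitive
        elif draw < 0.4:
            g48, g58 = "+", "+"      # active
        else:
            g48, g58 = "-", "-"      # destabilised beyond function
        calls.append(
            library.ScreenRecord(
                name=m.spec.name,
                growth48=library.GrowthCall.parse(g48),
                growth58=library.GrowthCall.parse(g58),
                position=m.spec.position,
            )
        )
    summary = library.screen_summary(calls)
    write_table(
        out / "screen_calls.tsv",
        pd.DataFrame(
            [
                {
                    "name": r.name, "growth48": r.growth48.value,
                    "growth58": r.growth58.value, "phenotype": r.phenotype.value,
                }
                for r in calls
            ]
        ),
    )

    # -- stage 4: growth kinetics ----------------------------------------
    growth_rows = []
    for label, mu, sub_seed in (
        ("control", cfg["mu_control"], child[3]),
        ("ts_mutant", cfg["mu_mutant"], child[3] + 1),
    ):
        curve = simulate.gen_growth_curve(
            mu=mu, noise_sd=cfg["growth_noise_sd"], seed=sub_seed
        )
        est = growth.fit_growth_curve(curve)
        growth_rows.append(
            {
                "strain": label, "mu_max": est.mu_max, "stderr": est.stderr,
                "window_start": est.window_start, "window_end": est.window_end,
            }
        )
    growth_df = pd.DataFrame(growth_rows)
    write_table(out / "growth_rates.tsv", growth_df)

    # -- stage 5: qPCR copy number ---------------------------------------
    dil = simulate.gen_dilution_series(
        eff=cfg["eff_target"], noise_sd=cfg["cq_noise_sd"], seed=child[4]
    )
    eff_fit = qpcr.fit_efficiency(dil)
    panel_df = simulate.gen_qpcr_panel(
        pcn_true=cfg["pcn_true"],
        eff_target=cfg["eff_target"],
        eff_ref=cfg["eff_ref"],
        noise_sd=cfg["cq_noise_sd"],
        seed=child[4] + 1,
    )
    panel = qpcr.panel_from_table(panel_df, cfg["eff_target"], cfg["eff_ref"])
    lod = qpcr.limit_of_detection(19.12, 31.09)
    pcn = qpcr.copy_number(panel, lod=lod)
    write_table(
        out / "copy_number.tsv",
        pd.DataFrame(
            [
                {
                    "sample": "ts_mutant", "pcn": pcn.pcn, "below_lod": pcn.below_lod,
                    "eff_target_fit_pct": eff_fit.percent, "lod": lod,
                }
            ]
        ),
    )

    # -- stage 6: plasmid stability ---------------------------------------
    psr_rows = []
    for label, q, sub_seed in (
        ("48C", cfg["loss_prob_permissive"], child[5]),
        ("55C", cfg["loss_prob_restrictive"], child[5] + 1),
    ):
        exp = simulate.gen_cfu_experiment(
            loss_prob=q, plating_cv=cfg["plating_cv"], seed=sub_seed
        )
        res = stability.psr_result(exp)
        psr_rows.append({"condition": label, "psr": res.psr, "regime": res.regime})
    psr_df = pd.DataFrame(psr_rows)
    write_table(out / "psr.tsv", psr_df)

    return {
        "n_regions": len(regions),
        "library_size": len(lib),
        "screen": summary["by_phenotype"],
        "mu_max": {r["strain"]: r["mu_max"] for r in growth_rows},
        "efficiency_pct": eff_fit.percent,
        "pcn": pcn.pcn,
        "lod": lod,
        "psr": {r["condition"]: r["psr"] for r in psr_rows},
    }
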