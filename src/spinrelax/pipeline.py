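"""End-to-end apo/holo comparison pipeline.

Runs the full analysis chain - simulate (or load) relaxation tables, fit
decay rates, estimate the global diffusion tensor, per-residue model-free
fitting, reduced spectral density mapping, titration classification - for
the ligand-free and ligand-bound states, and writes per-stage TSVs, a JSON
summary and overview figures into an output directory.  A run is fully
reproducible from its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import csp as csp_mod
from . import decay, diffusion, modelfree, rsdm, synthetic
from .physics import FieldParameters

__all__ = ["PipelineConfig", "run_apo_holo_comparison", "run_state"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable description of one comparison run."""

    # spectrometer and interaction constants
    proton_frequency: float = 600.13
    r_nh: float = 1.02
    csa: float = -160.0
    # synthetic scenario
    seed: int = 0
    noise: float = 0.02
    n_residues: int = 194
    # thresholds
    noe_cutoff: float = diffusion.NOE_CUTOFF
    trim_sd: float = diffusion.TRIM_SD_FACTOR
    f_test_alpha: float = modelfree.F_TEST_ALPHA
    broadening_ratio: float = csp_mod.DEFAULT_BROADENING_RATIO
    k_sigma: float = csp_mod.DEFAULT_K_SIGMA
    mc_reps: int = 50
    # titration stage (peak count is the full-length sequence and is
    # independent of a scaled-down relaxation run)
    titration_peaks: int = 194
    # stage toggles
    run_titration: bool = True
    make_plots: bool = True
    # outputs
    output_dir: str = "spinrelax_out"
    fragments: dict = dc_field(
        default_factory=lambda: {k: list(v) for k, v in synthetic.DEFAULT_FRAGMENTS.items()}
    )

    @property
    def field(self) -> FieldParameters:
        return FieldParameters(self.proton_frequency, self.r_nh, self.csa)

    @property
    def fragment_ranges(self) -> dict[str, tuple[int, int]]:
        return {k: tuple(v) for k, v in self.fragments.items()}

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or not data:
            raise ValueError(
                "empty or malformed config; expected a YAML mapping with keys "
                + ", ".join(f.name for f in dataclasses.fields(cls))
            )
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_state(config: PipelineConfig, mode: str) -> dict:
    """Run the relaxation chain for one state; returns stage artefacts."""
    scenario = synthetic.SyntheticScenario(
        mode=mode,
        n_residues=config.n_residues,
        fragments=config.fragment_ranges,
        noise=config.noise,
        seed=config.seed,
        field=config.field,
    )
    truth = synthetic.make_profile(scenario)
    t1, t2, noe = synthetic.simulate_relaxation_dataset(truth)
    relax_table = decay.fit_relaxation_table(t1, t2, noe)
    records = decay.records_from_table(relax_table)

    rigid = diffusion.select_rigid_residues(
        records, noe_cutoff=config.noe_cutoff, trim_sd=config.trim_sd
    )
    tensor = diffusion.fit_axially_symmetric(rigid, truth.orientations, config.field)

    mf_table = modelfree.run_modelfree(
        records,
        tensor,
        truth.orientations,
        config.field,
        mc_reps=config.mc_reps,
        seed=scenario.seed + 17,
        alpha=config.f_test_alpha,
    )

    triples = rsdm.map_records(records, config.field)
    frag_j = rsdm.fragment_average(triples, config.fragment_ranges)

    return dict(
        scenario=scenario,
        truth=truth,
        relax_table=relax_table,
        records=records,
        tensor=tensor,
        modelfree=mf_table,
        triples=triples,
        fragment_j=frag_j,
    )


def _fragment_mean(table: pd.DataFrame, col: str, ranges) -> dict[str, float]:
    out = {}
    for name, (lo, hi) in ranges.items():
        sel = table[(table["residue"] >= lo) & (table["residue"] <= hi) & ~table["flagged"]]
        out[name] = float(sel[col].mean())
    return out


def run_apo_holo_comparison(config: PipelineConfig) -> dict:
    """Full two-state comparison; writes TSVs, summary JSON and figures.

    Returns the summary dictionary (also written to summary.json).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    states = {}
    for mode in ("apo", "holo"):
        log.info("running %s state (seed %d)", mode, config.seed)
        states[mode] = run_state(config, mode)
        res = states[mode]
        decay.write_relaxation_table(res["relax_table"], out / f"rates_{mode}.tsv")
        res["modelfree"].to_csv(
            out / f"modelfree_{mode}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        jt = pd.DataFrame(
            dict(
                residue=[t.residue_id for t in res["triples"]],
                J0=[t.j0 for t in res["triples"]],
                J0_err=[t.j0_err for t in res["triples"]],
                JwN=[t.j_wn for t in res["triples"]],
                JwN_err=[t.j_wn_err for t in res["triples"]],
                JwH=[t.j_wh for t in res["triples"]],
                JwH_err=[t.j_wh_err for t in res["triples"]],
            )
        )
        jt.to_csv(out / f"rsdm_{mode}.tsv", sep="\t", index=False, float_format="%.6g")

    # delta-S2 (holo - apo) per residue
    apo_mf = states["apo"]["modelfree"].set_index("residue")
    holo_mf = states["holo"]["modelfree"].set_index("residue")
    common = apo_mf.index.intersection(holo_mf.index)
    ds2 = pd.DataFrame(
        dict(
            residue=common,
            S2_apo=apo_mf.loc[common, "S2"].to_numpy(),
            S2_holo=holo_mf.loc[common, "S2"].to_numpy(),
        )
    )
    ds2["delta_S2"] = ds2["S2_holo"] - ds2["S2_apo"]
    ds2.to_csv(out / "delta_s2.tsv", sep="\t", index=False, float_format="%.6g")

    titration = None
    if config.run_titration:
        holo_scn = states["holo"]["scenario"]
        class_map = synthetic.default_class_map(
            config.titration_peaks, seed=config.seed
        )
        series = synthetic.simulate_titration(class_map, holo_scn)
        report = csp_mod.classify_peaks(
            series,
            noise_floor=holo_scn.noise_floor,
            broadening_ratio=config.broadening_ratio,
            k_sigma=config.k_sigma,
        )
        report.classes.to_csv(
            out / "csp_classes.tsv", sep="\t", index=False, float_format="%.6g"
        )
        titration = report

    summary = _build_summary(config, states, ds2, titration)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    if config.make_plots:
        _make_plots(config, states, ds2, out)
    return summary


def _build_summary(config, states, ds2, titration) -> dict:
    frag = config.fragment_ranges
    summary: dict = {"seed": config.seed, "noise": config.noise, "states": {}}
    for mode, res in states.items():
        table = res["relax_table"]
        ok = table[~table["flagged"]]
        tensor = res["tensor"]
        mf = res["modelfree"]
        mf_ok = mf[~mf["flagged"]].copy()
        mf_ok["residue"] = mf_ok["residue"].astype(int)
        summary["states"][mode] = dict(
            mean_R1=float(ok["R1"].mean()),
            mean_R2=float(ok["R2"].mean()),
            mean_NOE=float(ok["NOE"].mean()),
            tensor=dict(
                tau_m_ns=tensor.tau_m * 1e9,
                anisotropy_ratio=tensor.anisotropy_ratio,
                axis_theta=tensor.axis_theta,
                axis_phi=tensor.axis_phi,
                chi2=tensor.chi2,
            ),
            fragment_S2_mean=_fragment_mean(
                mf_ok.assign(flagged=False), "S2", frag
            ),
            n_rex_residues=int(((mf_ok["Rex"] > 0) & mf_ok["model"].isin([3, 4])).sum()),
            fragment_J=res["fragment_j"].to_dict(orient="records"),
        )
    frag_means = {
        m: summary["states"][m]["fragment_S2_mean"] for m in ("apo", "holo")
    }
    summary["delta_S2"] = dict(
        n_residues=int(len(ds2)),
        fraction_positive_in_fragments=float(
            np.mean(
                [
                    d > 0
                    for r, d in zip(ds2["residue"], ds2["delta_S2"])
                    if any(lo <= r <= hi for lo, hi in frag.values())
                    and np.isfinite(d)
                ]
            )
        ),
        fragment_S2_increase={
            k: frag_means["holo"][k] - frag_means["apo"][k] for k in frag
        },
    )
    if titration is not None:
        summary["titration"] = dict(
            counts={
                k: int(titration.counts.get(k, 0))
                for k in ("vanished", "broadened", "shifted", "unperturbed")
            },
            shift_threshold_ppm=titration.shift_threshold,
        )
    return summary


def _make_plots(config, states, ds2, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for mode, res in states.items():
        table = res["relax_table"]
        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))
        for ax, col, err in (
            (axes[0], "R1", "R1_err"),
            (axes[1], "R2", "R2_err"),
            (axes[2], "NOE", "NOE_err"),
        ):
            ax.errorbar(
                table["residue"], table[col], yerr=table[err], fmt=".", ms=3, lw=0.5
            )
            ax.set_ylabel(col)
        for name, (lo, hi) in config.fragment_ranges.items():
            for ax in axes:
                ax.axvspan(lo, hi, alpha=0.15, color="tab:orange")
        axes[-1].set_xlabel("residue")
        fig.suptitle(f"{mode}: backbone 15N relaxation")
        fig.savefig(out / f"rates_{mode}.png", dpi=120)
        plt.close(fig)

        mf = res["modelfree"]
        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))
        axes[0].plot(mf["residue"], mf["S2"], ".", ms=3)
        axes[0].set_ylabel("S2")
        axes[1].plot(mf["residue"], mf["tau_e_ps"], ".", ms=3)
        axes[1].set_ylabel("tau_e (ps)")
        axes[2].plot(mf["residue"], mf["Rex"], ".", ms=3)
        axes[2].set_ylabel("Rex (1/s)")
        axes[-1].set_xlabel("residue")
        fig.suptitle(f"{mode}: model-free parameters")
        fig.savefig(out / f"modelfree_{mode}.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.axhline(0.0, color="k", lw=0.5)
    ax.plot(ds2["residue"], ds2["delta_S2"], ".", ms=3)
    for name, (lo, hi) in config.fragment_ranges.items():
        ax.axvspan(lo, hi, alpha=0.15, color="tab:orange")
    ax.set_xlabel("residue")
    ax.set_ylabel("S2(holo) - S2(apo)")
    fig.tight_layout()
    fig.savefig(out / "delta_s2.png", dpi=120)
    plt.close(fig)
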