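"""End-to-end orchestration of the comparative toy study.

Mirrors the four-system comparative design at desk scale: wild-type and
mutant dimers, each free or "clamped" (weak positional restraints on the
interface residues standing in for a crystallization nanobody), three
replicate seeds each.  Per variant it runs unbiased dynamics, end-state
energetics and fingerprints, plus adaptive-bias free-energy runs for the
free variants; across variants it reports ddG (both routes), the implied Kd
ratio, contact difference maps, an HbR-style table and an attenuation
summary (clamped-vs-free difference-map norms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abmd import (
    binding_dg,
    binding_result,
    pmf_from_bias,
    run_abmd,
    separation_cv,
    significance_ddg,
)
from .constants import DEFAULT_TEMPERATURE
from .dynamics import IntegratorConfig, run_cmd
from .endstate import EndstateConfig, binding_dg_frames
from .fingerprint import (
    contact_map,
    detect_hbonds,
    hbond_pair_counts,
    hbr_table,
    rmsf,
    subsample,
)
from .toysys import ToySystem, build_toy_dimer


@dataclass
class ExperimentPlan:
    """Study design: which variants, how many replicates, stage lengths."""

    n_receptor: int = 5
    n_ligand: int = 4
    variants: tuple = (
        ("WT", "free"),
        ("MUT", "free"),
        ("WT", "clamped"),
        ("MUT", "clamped"),
    )
    seeds: tuple = (1, 2, 3)
    build_seed: int = 0
    cmd_steps: int = 24000
    abmd_steps: int = 60000
    timestep: float = 5.0
    save_stride: int = 20
    temperature: float = DEFAULT_TEMPERATURE
    clamp_k: float = 2.0  # kcal/mol/A^2
    equilibration_fraction: float = 0.1
    tau: float = 1.0  # ps, flooding timescale
    cv_grid: tuple = (3.0, 18.0, 61)  # lo, hi, n_nodes over the separation CV
    bound_window: tuple = (3.0, 8.0)
    unbound_window: tuple = (12.0, 18.0)
    endstate_max_frames: int = 100
    fingerprint_max_frames: int = 300
    sasa_points: int = 242
    do_abmd: bool = True
    do_endstate: bool = True
    do_fingerprint: bool = True

    def __post_init__(self) -> None:
        if len(self.variants) < 1:
            raise ValueError("at least one variant is required")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replicate seeds must be distinct")


def interface_residues(system: ToySystem):
    """Residues on both chains that face an aligned partner."""
    n_aligned = min(
        len(system.receptor_residues), len(system.ligand_residues)
    )
    return np.concatenate(
        [system.receptor_residues[:n_aligned], system.ligand_residues[:n_aligned]]
    )


def apply_clamp(system: ToySystem, k: float | None = 2.0) -> ToySystem:
    """Weak positional restraints on interface residues of both chains.

    Models the rigidifying effect of a crystallization nanobody as an
    external clamp rather than a third molecule.  ``k`` of zero (or None)
    returns an unrestrained copy.
    """
    out = system.copy()
    if not k:
        return out
    beads = np.concatenate(
        [out.residue_beads(int(r)) for r in interface_residues(out)]
    )
    beads = np.sort(beads)
    out.restraints = (beads, out.bead_positions[beads].copy(), float(k))
    out.meta["clamped"] = True
    return out


def _subsampled(traj, max_frames):
    if traj.n_frames <= max_frames:
        return traj
    stride = int(np.ceil(traj.n_frames / max_frames))
    return traj.sliced(subsample(np.arange(traj.n_frames), stride))


def run_experiment(plan: ExperimentPlan) -> dict:
    """Execute the study plan; returns a nested report bundle.

    Any stage failure is recorded in ``bundle["failures"]`` and the bundle
    stays partial rather than aborting the run.
    """
    bundle: dict = {"plan": plan, "variants": {}, "cross": {}, "failures": []}

    for variant, condition in plan.variants:
        key = (variant, condition)
        system = build_toy_dimer(
            plan.n_receptor, plan.n_ligand, variant, plan.build_seed
        )
        if condition == "clamped":
            system = apply_clamp(system, plan.clamp_k)
        entry: dict = {"seeds": {}}
        bundle["variants"][key] = entry

        for seed in plan.seeds:
            res: dict = {}
            entry["seeds"][seed] = res
            config = IntegratorConfig(
                timestep=plan.timestep,
                temperature=plan.temperature,
                n_steps=plan.cmd_steps,
                save_stride=plan.save_stride,
                seed=seed,
            )
            try:
                traj = run_cmd(system, config).discard_equilibration(
                    plan.equilibration_fraction
                )
            except Exception as exc:  # noqa: BLE001 - stage failures go to the manifest
                bundle["failures"].append((key, seed, "cmd", repr(exc)))
                continue

            if plan.do_endstate:
                try:
                    decomp = binding_dg_frames(
                        _subsampled(traj, plan.endstate_max_frames),
                        system,
                        config=EndstateConfig(
                            temperature=plan.temperature,
                            sasa_points=plan.sasa_points,
                        ),
                    )
                    res["dg_endstate"] = decomp.dg_binding
                    res["dg_endstate_se"] = decomp.dg_se
                except Exception as exc:  # noqa: BLE001
                    bundle["failures"].append((key, seed, "endstate", repr(exc)))

            if plan.do_fingerprint:
                try:
                    ftraj = _subsampled(traj, plan.fingerprint_max_frames)
                    cmap = contact_map(ftraj, system)
                    res["contact_map"] = cmap
                    per_frame = [
                        len(detect_hbonds(system, ftraj.coords[f], frame=f))
                        for f in range(ftraj.n_frames)
                    ]
                    res["hbond_per_frame"] = np.asarray(per_frame)
                    res["hbond_total"] = int(np.sum(per_frame))
                    pair_counts = hbond_pair_counts(ftraj, system)
                    res["hbond_pair_counts"] = {
                        f"{system.residue_names[i]}-{system.residue_names[j]}": c
                        for (i, j), c in pair_counts.items()
                    }
                    res["rmsf"] = rmsf(ftraj, system)
                except Exception as exc:  # noqa: BLE001
                    bundle["failures"].append((key, seed, "fingerprint", repr(exc)))

            if plan.do_abmd and condition == "free":
                try:
                    lo, hi, n = plan.cv_grid
                    state, _ = run_abmd(
                        system,
                        separation_cv(system),
                        IntegratorConfig(
                            timestep=plan.timestep,
                            temperature=plan.temperature,
                            n_steps=plan.abmd_steps,
                            save_stride=plan.save_stride,
                            seed=seed + 1000,
                        ),
                        np.linspace(lo, hi, int(n)),
                        tau=plan.tau,
                    )
                    pmf = pmf_from_bias(state)
                    res["dg_abmd"] = binding_dg(
                        pmf, plan.bound_window, plan.unbound_window
                    )
                    res["abmd_converged"] = state.converged
                except Exception as exc:  # noqa: BLE001
                    bundle["failures"].append((key, seed, "abmd", repr(exc)))

    _cross_analyses(bundle, plan)
    return bundle


def _mean_contact_map(entry):
    maps = [
        s["contact_map"].frequencies
        for s in entry["seeds"].values()
        if "contact_map" in s
    ]
    return np.mean(maps, axis=0) if maps else None


def _collect(entry, field_name):
    return [s[field_name] for s in entry["seeds"].values() if field_name in s]


def _cross_analyses(bundle: dict, plan: ExperimentPlan) -> None:
    v = bundle["variants"]
    cross = bundle["cross"]
    wt_free, mut_free = ("WT", "free"), ("MUT", "free")
    wt_cl, mut_cl = ("WT", "clamped"), ("MUT", "clamped")

    if wt_free in v and mut_free in v:
        for method, field_name in (("ABMD", "dg_abmd"), ("MMPBSA", "dg_endstate")):
            dgs_wt = _collect(v[wt_free], field_name)
            dgs_mut = _collect(v[mut_free], field_name)
            if dgs_wt and dgs_mut:
                result = binding_result(
                    dgs_wt, dgs_mut, T=plan.temperature, method=method
                )
                cross[f"binding_{method.lower()}"] = result
                paired = [m - w for m, w in zip(dgs_mut, dgs_wt)]
                if len(paired) >= 2:
                    cross[f"p_{method.lower()}"] = significance_ddg(paired)

        totals_wt = _collect(v[wt_free], "hbond_total")
        totals_mut = _collect(v[mut_free], "hbond_total")
        if totals_wt and totals_mut:
            cross["hbond_totals"] = {"WT": totals_wt, "MUT": totals_mut}

        m_wt, m_mut = _mean_contact_map(v[wt_free]), _mean_contact_map(v[mut_free])
        if m_wt is not None and m_mut is not None:
            diff = m_mut - m_wt
            cross["contact_diff_free"] = diff
            cross["diff_norm_free"] = float(np.abs(diff).mean())

    if wt_cl in v and mut_cl in v:
        m_wt, m_mut = _mean_contact_map(v[wt_cl]), _mean_contact_map(v[mut_cl])
        if m_wt is not None and m_mut is not None:
            diff = m_mut - m_wt
            cross["contact_diff_clamped"] = diff
            cross["diff_norm_clamped"] = float(np.abs(diff).mean())

    if "diff_norm_free" in cross and "diff_norm_clamped" in cross:
        cross["attenuation"] = cross["diff_norm_clamped"] < cross["diff_norm_free"]

    # HbR-style table: clamped plays the nanobody-present condition
    have = all(k in v for k in (wt_cl, mut_cl, wt_free, mut_free))
    if have:
        tabs = {}
        for key in (wt_cl, mut_cl, wt_free, mut_free):
            pooled: dict = {}
            for s in v[key]["seeds"].values():
                for pair, c in s.get("hbond_pair_counts", {}).items():
                    pooled[pair] = pooled.get(pair, 0) + c
            tabs[key] = pooled
        if any(tabs.values()):
            cross["hbr_table"] = hbr_table(
                tabs[wt_cl], tabs[mut_cl], tabs[wt_free], tabs[mut_free]
            )


def render_report(bundle: dict) -> str:
    """Deterministic markdown/TSV summary of a report bundle."""
    lines = ["# deltabind comparative report", ""]
    plan = bundle.get("plan")
    if plan is not None:
        lines.append(
            f"Variants: {len(plan.variants)}; replicates: {len(plan.seeds)}; "
            f"T = {plan.temperature:.1f} K"
        )
        lines.append("")

    cross = bundle.get("cross", {})
    binding_keys = [k for k in ("binding_abmd", "binding_mmpbsa") if k in cross]
    if binding_keys:
        lines.append("## Binding free energies (kcal/mol)")
        lines.append("method\tdG_WT\tdG_MUT\tddG\tKd_ratio")
        for k in binding_keys:
            r = cross[k]
            lines.append(
                f"{r.method}\t{r.dg_wt:.2f} +/- {r.dg_wt_unc:.2f}"
                f"\t{r.dg_mut:.2f} +/- {r.dg_mut_unc:.2f}"
                f"\t{r.ddg:.2f} +/- {r.ddg_unc:.2f}\t{r.kd_ratio:.2f}"
            )
        lines.append("")

    if "hbond_totals" in cross:
        t = cross["hbond_totals"]
        lines.append("## Interface hydrogen bonds (totals per replicate)")
        lines.append(f"WT\t{t['WT']}")
        lines.append(f"MUT\t{t['MUT']}")
        lines.append("")

    if "hbr_table" in cross:
        lines.append("## Hydrogen-bond ratio table (clamped = nanobody-present)")
        lines.append("pair\tTLV\tTdELV\tHbR1\tTL\tTdEL\tHbR2\tflag")
        for _, row in cross["hbr_table"].iterrows():
            lines.append(
                f"{row['pair']}\t{row['tlv']}\t{row['tdelv']}\t{row['hbr1_display']}"
                f"\t{row['tl']}\t{row['tdel']}\t{row['hbr2_display']}\t{row['flag']}"
            )
        lines.append("")

    if "diff_norm_free" in cross or "diff_norm_clamped" in cross:
        lines.append("## Difference-map norms (mean |MUT - WT| contact frequency)")
        if "diff_norm_free" in cross:
            lines.append(f"free\t{cross['diff_norm_free']:.4f}")
        if "diff_norm_clamped" in cross:
            lines.append(f"clamped\t{cross['diff_norm_clamped']:.4f}")
        if "attenuation" in cross:
            lines.append(f"clamp_attenuates_difference\t{cross['attenuation']}")
        lines.append("")

    failures = bundle.get("failures", [])
    if failures:
        lines.append("## Failure manifest")
        for item in failures:
            lines.append(f"{item}")
        lines.append("")
    return "\n".join(lines) + "\n"
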