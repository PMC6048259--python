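# deltabind

A desk-scale pipeline for quantifying how a single-residue interface
perturbation weakens protein–protein binding, built around the comparative
design used to study the dystonia-linked TorsinA ΔE303 deletion and its
activator LULL1: wild-type and mutant complexes, with and without a
rigidifying crystallization agent, compared by binding free energies and
interaction fingerprints.

Because the original microsecond all-atom trajectories are not reproducible
at desk scale, the pipeline runs on coarse-grained bead dimers whose wild
type (WT) and mutant (MUT) differ only in a declared set of interface
parameters — a parameter-level analogue of deleting one interface residue.
Every analysis stage is nonetheless the real method, implemented in full:

- **Langevin dynamics** (BAOAB splitting, collision frequency 2 ps⁻¹,
  310 K) on bead systems with harmonic bonds, Lennard-Jones and screened
  Coulomb terms.
- **Gaussian-accelerated sampling (GaMD):** a harmonic boost
  ΔV = ½k(E − V)² applied below a threshold E, with
  k = k₀/(V_max − V_min), k₀ = min(1, (σ₀/σ_V)·(V_max − V_min)/(V_max − V̄)),
  and canonical reweighting of binned reaction coordinates by per-bin
  averages of e^{ΔV/k_BT} — either the exact exponential average or its
  second-order cumulant expansion — followed by F(RC) = −k_BT ln p(RC).
- **Adaptive-bias free-energy sampling (ABMD):** flooding along distance /
  angle / torsion collective variables built on anchor-group centres of
  mass; at convergence the negated bias is the PMF, and
  ΔG_bind = −k_BT ln(∫_bound e^{−F/k_BT} / ∫_unbound e^{−F/k_BT}).
- **End-state energetics (MM-PBSA-style):** per-frame
  ΔG ≈ ΔE_MM + ΔG_sol − TΔS with ΔE_MM = ΔE_int + ΔE_elec + ΔE_vdW and
  ΔG_sol = ΔG_pol + γ·ΔSASA (γ = 0.0072 kcal/mol/Å²); polar solvation is a
  screened generalized-Born surrogate; −TΔS is carried but flagged not
  computed; exact per-residue decomposition.
- **Fingerprints:** residue contacts (centre-of-mass distance ≤ 6 Å),
  hydrogen bonds (donor–acceptor ≤ 3.0 Å and acceptor–H–donor ≥ 135°),
  HbR ratio tables with the nanobody-stabilisation flag, difference maps,
  RMSD/RMSF, native-contact fractions, and ΔΔG → K_d fold-change
  (K_d ratio = e^{ΔΔG/k_BT}).

Intended users: computational structural biologists who want a tested,
inspectable reference implementation of this analysis stack, exercised
end-to-end on systems small enough for a laptop.

## Worked example

The arithmetic stages run directly on the published reference tables
shipped in `deltabind.datasets`:

```python
import deltabind as db
from deltabind.datasets import BINDING_DG_TABLE, hbond_count_dicts

for method in ("ABMD", "MMPBSA"):
    e = BINDING_DG_TABLE[method]
    ddg, _ = db.delta_delta_g(e["dg_mut"][0], e["dg_wt"][0])
    print(method, "ddG = %.2f kcal/mol, Kd ratio = %.2f"
          % (ddg, db.kd_ratio(ddg, 310.0)))

table = db.hbr_table(*hbond_count_dicts()).set_index("pair")
row = table.loc["D262-W489"]
print("D262-W489: HbR1=%s HbR2=%s flag=%s"
      % (row.hbr1_display, row.hbr2_display, row.flag))
```

prints

```
ABMD ddG = 4.67 kcal/mol, Kd ratio = 1960.15
MMPBSA ddG = 5.23 kcal/mol, Kd ratio = 4864.98
D262-W489: HbR1=2.04 HbR2=0.37 flag=Yes
```

ΔΔG > 0 means the mutant binds its activator more weakly; the K_d ratios
say the dissociation constant grows by three orders of magnitude. For the
hydrogen-bond pair D262–W489, HbR1 > HbR2 flags that the mutant complex
keeps unusually many hydrogen bonds only when the crystallization nanobody
is present — the stabilisation artefact the comparative design is built to
expose.

The full simulation study runs from the shell:

```sh
deltabind run -o report.md            # WT/MUT x free/clamped, 3 seeds each
deltabind build --variant MUT -o mut.pdb
deltabind cmd --system mut.pdb --steps 20000 -o mut.dtj
deltabind fingerprint --traj mut.dtj --system mut.pdb -o maps/
```

The report contains the ΔG/ΔΔG/K_d block, per-pair hydrogen-bond ratios,
and the clamped-vs-free difference-map norms showing that clamping the
interface (the nanobody stand-in) attenuates the WT-vs-MUT differences.

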