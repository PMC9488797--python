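"""Microbiota readouts: hydrogen production, cell densities, metabolite pools.

Dark/light hydrogen AUC per colonized mouse is adjusted by cecal mass
(regression-based, the microbiota-mass proxy) and compared between the
gnotobiotic and SPF groups; bead-normalized cytometry gives absolute cecal
densities; cecal metabolite concentrations are converted to total pools
(concentration x cecal mass) with propagated uncertainty.
"""

from pathlib import Path

import pandas as pd

from isocal.balance import cecal_metabolite_pool, from_samples
from isocal.cytometry import CytometryAssay, density_from_events
from isocal.group_stats import anova_tukey
from isocal.io import read_profiles
from isocal.normalization import adjust_hydrogen

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    res = ROOT / "results"
    per_mouse = pd.read_csv(res / "per_mouse_phase_means.csv")
    profiles = read_profiles(res / "synthetic" / "profiles.csv")
    assays = pd.read_csv(res / "synthetic" / "cytometry.csv")
    mets = pd.read_csv(res / "synthetic" / "metabolites.csv")

    # hydrogen: colonized groups only (germ-free traces sit at the blank)
    colonized = profiles[profiles["group"] != "GF"]
    rows = []
    for phase in ("light", "dark"):
        sub = per_mouse[(per_mouse["phase"] == phase)].merge(colonized, on="mouse_id")
        fit = adjust_hydrogen(sub["h2_auc"], sub["cecal_mass_g"], groups=sub["group"])
        table = anova_tukey(fit.adjusted, sub["group"])
        p = table["p_adj"].iloc[0]
        means = pd.Series(fit.adjusted).groupby(sub["group"].to_numpy()).mean()
        print(
            f"{phase}: cecal-mass-adjusted H2 AUC  "
            + "  ".join(f"{g}={v:.0f}" for g, v in means.items())
            + f"  (OLIGO vs SPF p = {p:.4f})"
        )
        rows.append(table.assign(phase=phase))
    pd.concat(rows).to_csv(res / "hydrogen_adjusted_comparisons.csv", index=False)

    blank = int(assays.loc[assays["group"] == "GF", "bacterial_events"].max())
    dens_rows = []
    for _, r in assays.iterrows():
        d = density_from_events(
            CytometryAssay(
                bacterial_events=int(r["bacterial_events"]),
                bead_events=int(r["bead_events"]),
                sample_mass_g=float(r["sample_mass_g"]),
            ),
            blank_events=blank,
        )
        dens_rows.append({"mouse_id": r["mouse_id"], "group": r["group"], **d})
    dens = pd.DataFrame(dens_rows)
    dens.to_csv(res / "cecal_densities.csv", index=False)
    for group, g in dens[~dens["at_blank"]].groupby("group"):
        print(f"cecal density {group}: {g['cells_per_g'].mean():.3g} cells/g")

    # total cecal pools: group-level concentration x group-level cecal mass
    pool_rows = []
    cecal_by_group = {
        g: from_samples(v["cecal_mass_g"]) for g, v in profiles.groupby("group")
    }
    for (group, phase, met), g in mets.groupby(["group", "phase", "metabolite"]):
        conc = from_samples(g["conc_umol_per_g"])
        pool = cecal_metabolite_pool(conc, cecal_by_group[group])
        pool_rows.append(
            {
                "group": group,
                "phase": phase,
                "metabolite": met,
                "pool_umol": pool.mean,
                "u": pool.u,
            }
        )
    pools = pd.DataFrame(pool_rows)
    pools.to_csv(res / "cecal_metabolite_pools.csv", index=False)
    wide = pools[pools["metabolite"] == "acetate"].pivot_table(
        index="phase", columns="group", values="pool_umol"
    )
    print("total cecal acetate pools (umol):")
    print(wide.round(1).to_string())


if __name__ == "__main__":
    main()
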