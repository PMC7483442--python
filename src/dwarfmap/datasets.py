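"""Bundled worked-example tables for the watermelon dwarfism analysis.

Two small in-memory datasets accompany the package so every screening
operation can be exercised end to end without external files:

* :func:`ga_hormone_panel` — endogenous gibberellin levels (ng/g fresh
  weight; mean ± SD of three UPLC-MS/MS runs) in shoots of the dwarf and
  vine parents and of dwarf and vine F2 plants.  ``n.d.`` (not detected)
  and ``n.q.`` (not quantifiable) entries are carried as status flags.
* :func:`ga_gene_fpkm` — FPKM triplicates for the 20 expressed GA
  biosynthetic/metabolic genes in vine (V) and dwarf (D) F2 shoots, with
  the originally reported direction label for reference.
"""

from __future__ import annotations

import pandas as pd

from .quant_compare import GroupMeasurement

# (analyte, CG vine parent, w106 dwarf parent, F2 vine, F2 dwarf); entries
# are (mean, sd) in ng/g fresh weight over n=3 runs, or "n.d."/"n.q."
_GA_PANEL = [
    ("GA_1", (0.0152, 0.0003), (0.0210, 0.0016), (0.0270, 0.0007), (0.0230, 0.0004)),
    ("GA_3", "n.d.", (0.0527, 0.0027), (0.0268, 0.0010), (0.1029, 0.0034)),
    ("GA_4", (0.1074, 0.0026), (0.0118, 0.0011), (0.0900, 0.0064), (0.0176, 0.0016)),
    ("GA_5", (0.0223, 0.0020), (0.0225, 0.0006), (0.0216, 0.0007), (0.0217, 0.0009)),
    ("GA_6", (0.0081, 0.0002), (0.0100, 0.0012), "n.d.", (0.0084, 0.0014)),
    ("GA_7", "n.q.", "n.q.", "n.d.", "n.q."),
    ("GA_8", (0.0256, 0.0039), (0.0275, 0.0018), (0.0275, 0.0009), (0.0325, 0.0028)),
    ("GA_9", (0.0494, 0.0016), (0.0452, 0.0016), (0.0371, 0.0012), (0.0992, 0.0046)),
    ("GA_12", (0.0882, 0.0088), (0.0516, 0.0044), (0.0466, 0.0080), (0.0362, 0.0014)),
    ("GA_15", "n.d.", (0.0882, 0.0025), "n.d.", "n.d."),
    ("GA_19", (0.1935, 0.0135), (0.3053, 0.0220), (0.1906, 0.0208), (0.1770, 0.0183)),
    ("GA_20", (0.0394, 0.0081), (0.0309, 0.0011), (0.0329, 0.0034), (0.0469, 0.0038)),
    ("GA_24", (0.0800, 0.0013), (0.0652, 0.0019), (0.0633, 0.0021), (0.0575, 0.0022)),
    ("GA_29", (0.0607, 0.0015), (0.1136, 0.0018), (0.0549, 0.0005), (0.2391, 0.0045)),
    ("GA_34", (0.0364, 0.0023), "n.d.", "n.d.", "n.q."),
    ("GA_44", (0.1218, 0.0017), (0.1695, 0.0158), (0.1193, 0.0075), "n.q."),
    ("GA_51", (0.0187, 0.0016), (0.0277, 0.0025), (0.0239, 0.0024), (0.0263, 0.0034)),
    ("GA_53", (0.0093, 0.0005), (0.0152, 0.0011), (0.0058, 0.0008), (0.0044, 0.0008)),
]

GA_PANEL_GROUPS = ("CG_vine_parent", "w106_dwarf_parent", "F2_vine", "F2_dwarf")

_FPKM_ROWS = [
    ("Cla006048", "Ent-copalyl diphosphate synthase (CPS)", 4.76, 10.14, 5.55, 7.06, 6.49, 8.06, "Up"),
    ("Cla005482", "Ent-kaurene synthase 1 (KS)", 9.53, 8.75, 8.23, 11.12, 11.21, 13.53, "Up"),
    ("Cla020710", "Ent-kaurene oxidase (KO)", 12.92, 13.62, 10.71, 28.40, 24.53, 29.08, "Up (sig)"),
    ("Cla006992", "Ent-kaurenoic acid oxidase 1 (KAO)", 14.56, 24.91, 31.02, 23.16, 16.90, 20.05, "Down"),
    ("Cla021351", "Ent-kaurenoic acid oxidase 1 (KAO)", 1.66, 1.41, 1.27, 1.72, 1.20, 1.42, "-"),
    ("Cla002362", "Gibberellin 20-oxidase (GA20ox)", 1.39, 0.43, 1.08, 9.77, 10.05, 10.28, "Up (sig)"),
    ("Cla006227", "Gibberellin 20-oxidase (GA20ox)", 0.00, 0.00, 0.00, 0.71, 0.16, 0.38, "Up (sig)"),
    ("Cla006941", "Gibberellin 20-oxidase (GA20ox)", 0.47, 0.52, 1.17, 1.03, 0.30, 0.44, "Down"),
    ("Cla008413", "Gibberellin 20-oxidase (GA20ox)", 0.00, 0.00, 0.04, 0.28, 0.18, 0.67, "Up (sig)"),
    ("Cla010726", "Gibberellin 20-oxidase-like protein (GA20ox)", 3.98, 3.64, 3.63, 5.68, 5.27, 5.58, "Up"),
    ("Cla013892", "Gibberellin 20-oxidase (GA20ox)", 0.09, 0.16, 0.04, 0.19, 0.18, 0.26, "Up"),
    ("Cla015407", "Gibberellin 3-beta-hydroxylase (GA3ox)", 4.56, 3.86, 4.13, 11.86, 12.36, 10.67, "Up (sig)"),
    ("Cla022285", "Gibberellin 3-beta-hydroxylase (GA3ox)", 0.05, 0.00, 0.00, 0.30, 0.14, 0.04, "Up"),
    ("Cla005259", "Gibberellin 2-beta-dioxygenase 8 (GA2ox)", 0.00, 0.00, 0.19, 0.00, 0.11, 0.52, "Up"),
    ("Cla005397", "Gibberellin 2-oxidase (GA2ox)", 2.92, 8.67, 2.63, 3.29, 4.50, 2.05, "Down"),
    ("Cla007482", "Gibberellin 2-beta-dioxygenase 8 (GA2ox)", 1.53, 1.35, 1.24, 1.13, 1.31, 1.95, "Up"),
    ("Cla009774", "Gibberellin 2-oxidase (GA2ox)", 0.00, 0.18, 0.17, 0.27, 0.36, 0.05, "Up"),
    ("Cla015162", "Gibberellin 2-oxidase (GA2ox)", 0.05, 0.05, 0.00, 0.84, 0.72, 0.75, "Up (sig)"),
    ("Cla017338", "Gibberellin 2-oxidase 2 (GA2ox)", 0.00, 0.00, 0.05, 0.62, 0.03, 0.20, "Up"),
    ("Cla019586", "Gibberellin 2-oxidase (GA2ox)", 0.32, 1.53, 0.87, 6.71, 3.51, 9.32, "Up (sig)"),
]


def ga_hormone_panel() -> pd.DataFrame:
    """Gibberellin panel in long form: analyte, group, mean, sd, n, status."""
    rows = []
    for analyte, *groups in _GA_PANEL:
        for group_name, entry in zip(GA_PANEL_GROUPS, groups):
            if isinstance(entry, str):
                rows.append((analyte, group_name, None, None, 3, entry))
            else:
                rows.append((analyte, group_name, entry[0], entry[1], 3, "quantified"))
    return pd.DataFrame(rows, columns=["analyte", "group", "mean", "sd", "n", "status"])


def ga_hormone_measurements(group_a: str = "F2_vine",
                            group_b: str = "F2_dwarf") -> list[GroupMeasurement]:
    """The panel as GroupMeasurement pairs (``group_b`` relative to ``group_a``)."""
    panel = ga_hormone_panel()
    out = []
    for analyte, grp in panel.groupby("analyte", sort=False):
        a = grp.loc[grp["group"] == group_a].iloc[0]
        b = grp.loc[grp["group"] == group_b].iloc[0]
        out.append(GroupMeasurement(
            analyte=analyte,
            mean_a=a["mean"], sd_a=a["sd"], n_a=int(a["n"]),
            mean_b=b["mean"], sd_b=b["sd"], n_b=int(b["n"]),
            status_a=a["status"], status_b=b["status"],
        ))
    return out


def ga_gene_fpkm() -> pd.DataFrame:
    """FPKM triplicates of GA pathway genes: V_1..V_3 (vine), D_1..D_3 (dwarf)."""
    cols = ["gene", "annotation", "V_1", "V_2", "V_3", "D_1", "D_2", "D_3",
            "reported_direction"]
    return pd.DataFrame(_FPKM_ROWS, columns=cols)
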