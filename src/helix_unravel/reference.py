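"""Reported reference results for Aβ(13-26) central-helix unfolding ensembles.

These tables summarise previously reported all-atom simulation ensembles of
the wild-type and mutant Aβ(13-26) central helix at 360 K: per-trajectory
last-2-ns averages with group labels, the published column means/SDs, the
three-step unfolding timetable of the five completely unfolding wild-type
trajectories, and the per-residue nonpolar interaction energies at step 2.
They serve as ground truth for validating the classifier, the summary
statistics and the energy bookkeeping identities, and as reference inputs
for reproduction runs — they are *data*, not quantities computed by this
package.

Column conventions: RMSD in Å, energies in kcal/mol, times in ns, αHB
counts dimensionless.  ``+``/``0`` denote protonated/neutral histidines.
"""

from __future__ import annotations

__all__ = [
    "LAST2NS_TABLES",
    "PRINTED_STATS",
    "STEP_TIMETABLE",
    "PER_RESIDUE_ENPNP_STEP2",
    "SALT_BRIDGE_FORMED_A",
    "SALT_BRIDGE_INITIAL_A",
    "iter_label_rows",
]

# Per-trajectory last-2-ns averages:
# trajectory -> (rmsd+, rmsd0, hbs+, hbs0, group+, group0)
LAST2NS_TABLES: dict[str, dict[int, tuple]] = {
    "WT": {
        1: (2.59, 4.36, 2.4, 0.1, "B", "C"),
        2: (2.79, 1.25, 2.8, 4.1, "B", "A"),
        3: (2.20, 1.35, 2.5, 3.8, "B", "A"),
        4: (5.25, 1.14, 0.0, 3.6, "C", "A"),
        5: (3.84, 4.37, 0.9, 1.6, "B", "B"),
        6: (2.29, 1.40, 1.8, 4.1, "B", "A"),
        7: (4.85, 1.23, 0.4, 3.8, "C", "A"),
        8: (3.18, 3.59, 1.8, 1.4, "B", "B"),
        9: (4.89, 4.02, 0.1, 0.0, "C", "C"),
        10: (1.24, 1.82, 4.2, 2.6, "A", "A"),
    },
    "MA": {
        1: (0.74, 1.24, 4.4, 4.3, "A", "A"),
        2: (1.03, 1.23, 4.1, 4.5, "A", "A"),
        3: (4.72, 4.03, 1.9, 1.1, "B", "B"),
        4: (0.83, 0.64, 4.2, 4.4, "A", "A"),
        5: (2.23, 0.77, 3.6, 4.2, "B", "A"),
    },
    "ML": {
        1: (2.97, 0.69, 1.8, 4.3, "B", "A"),
        2: (0.85, 1.39, 4.6, 4.3, "A", "A"),
        3: (1.27, 2.46, 4.2, 2.3, "A", "B"),
        4: (1.25, 3.18, 4.0, 1.1, "A", "B"),
        5: (1.10, 1.24, 4.5, 4.3, "A", "A"),
    },
}

# Published column means and SDs: variant -> column -> (mean, sd).
# Columns are (rmsd, "+"/"0") at 2 dp and (hbs, "+"/"0") at 1 dp.
PRINTED_STATS: dict[str, dict[tuple, tuple]] = {
    "WT": {
        ("rmsd", "+"): (3.31, 1.35), ("rmsd", "0"): (2.45, 1.43),
        ("hbs", "+"): (1.7, 1.3), ("hbs", "0"): (2.5, 1.6),
    },
    "MA": {
        ("rmsd", "+"): (1.91, 1.68), ("rmsd", "0"): (1.58, 1.39),
        ("hbs", "+"): (3.6, 1.0), ("hbs", "0"): (3.7, 1.5),
    },
    "ML": {
        ("rmsd", "+"): (1.49, 0.84), ("rmsd", "0"): (1.79, 1.01),
        ("hbs", "+"): (3.8, 1.1), ("hbs", "0"): (3.2, 1.5),
    },
}

# Three-step timetable of the five completely unfolding WT trajectories:
# label -> dict with per-step (time ns, rmsd Å, marker), where the marker is
# the αHB count at step 1, E_np-np at step 2 and E_p-p at step 3.
STEP_TIMETABLE: dict[str, dict[str, tuple]] = {
    "WT+4": {"step1": (4.28, 1.47, 3), "step2": (4.59, 3.01, -73.58),
             "step3": (5.29, 5.51, -116.13)},
    "WT+7": {"step1": (0.10, 0.93, 2), "step2": (0.15, 2.19, -66.32),
             "step3": (1.36, 4.26, -113.67)},
    "WT+9": {"step1": (15.21, 2.85, 0), "step2": (15.53, 2.93, -68.76),
             "step3": (16.43, 3.85, -70.04)},
    "WT01": {"step1": (17.05, 2.63, 1), "step2": (17.15, 3.22, -74.15),
             "step3": (18.15, 3.99, -95.04)},
    "WT09": {"step1": (9.09, 1.54, 1), "step2": (9.20, 2.18, -73.54),
             "step3": (10.65, 4.61, -87.82)},
}

# Per-residue E_np-np (kcal/mol) at step 2 for the same five trajectories,
# ordered L17, V18, F19, F20, A21, V24, G25.
PER_RESIDUE_ENPNP_STEP2: dict[str, tuple[float, ...]] = {
    "WT+4": (-21.64, -23.68, -22.65, -35.79, -18.93, -16.03, -8.43),
    "WT+7": (-16.43, -18.93, -23.41, -33.52, -21.74, -10.69, -7.91),
    "WT+9": (-14.33, -22.93, -20.15, -29.62, -20.21, -18.70, -11.59),
    "WT01": (-18.37, -24.10, -26.16, -33.74, -20.85, -14.35, -10.74),
    "WT09": (-21.75, -26.40, -26.52, -28.42, -21.85, -13.96, -8.18),
}

#: Reported Nζ(K16)-Cγ(D23) distances (Å): formed salt bridge vs the
#: initial energy-minimised structure.
SALT_BRIDGE_FORMED_A = 3.36
SALT_BRIDGE_INITIAL_A = 8.86


def iter_label_rows():
    """Yield (variant, trajectory, protonation, avg_rmsd, avg_hbs, group)
    for all 40 reported trajectories."""
    for variant, table in LAST2NS_TABLES.items():
        for traj, (r_p, r_0, h_p, h_0, g_p, g_0) in table.items():
            yield variant, traj, "+", r_p, h_p, g_p
            yield variant, traj, "0", r_0, h_0, g_0
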