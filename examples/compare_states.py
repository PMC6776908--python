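"""Structural geometry between two conformational states.

Uses the synthetic translocon-like two-state construct: a ten-helix
bundle (chain Y) with an accessory helical hairpin (chain E).  In the
"bound" state one gate helix is tilted by 5 degrees and another is
shifted 5 A toward the pore; the hairpin is tilted 30 degrees from the
membrane normal.  All three programmed magnitudes are recovered by the
measurement machinery (bundle-normal estimation, hairpin tilt,
inter-state helix tilt via a chain map, per-residue CA displacement).
"""

import gatescope as gs

toy = gs.make_translocon_toy(
    tmh7_tilt_deg=5.0, tmh2b_shift=5.0, hairpin_tilt_deg=30.0
)

# fit on the helices that do not move between states
fit_expr = "chain Y and (" + " or ".join(
    f"resid {h.first_residue}-{h.last_residue}"
    for i, h in enumerate(toy["helices"]) if i in (5, 7, 8, 9)
) + ")"

normal = gs.membrane_normal(toy["bound"], "chain Y")
hairpin_tilt = gs.helix_tilt(toy["bound"], toy["hairpin"], normal)
tmh7_tilt = gs.interstate_helix_tilt(
    toy["bound"], toy["relaxed"], toy["tmh7"], fit_expr, toy["chain_map"]
)
h2b = toy["tmh2b"]
field = gs.displacement_field(
    toy["bound"], toy["relaxed"], fit_expr,
    f"chain Y and resid {h2b.first_residue}-{h2b.last_residue}",
    chain_map=toy["chain_map"],
)

print(f"hairpin tilt vs bundle normal: {hairpin_tilt:5.2f} deg (programmed 30)")
print(f"inter-state tilt of the gate helix: {tmh7_tilt:5.2f} deg (programmed 5)")
print(f"max CA displacement of the shifted helix: "
      f"{field.magnitudes.max():5.2f} A (programmed 5)")
print("On deposited structures the same calls quantify how a helical gate "
      "rearranges between functional states of a membrane protein.")
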