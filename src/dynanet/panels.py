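"""Built-in mediator panel registries.

The human serum panel is the 25-plex Luminex kit (26 analytes incl. GDF-15)
plus HMGB1 (ELISA) and nitrite+nitrate (nitrate reductase), 28 mediators in
total.  The mouse hepatocyte-supernatant panel is the 20-plex kit plus
HMGB1, nitrite+nitrate and GDF-15, 23 in total.  Arbitrary panels are
accepted everywhere; these are conveniences for presets and display order.
"""

HUMAN_PANEL = (
    "Eotaxin",
    "GDF-15",
    "GM-CSF",
    "IFN-a2",
    "IFN-g",
    "IL-1b",
    "IL-1RA",
    "IL-2",
    "sIL-2Ra",
    "IL-4",
    "IL-5",
    "IL-6",
    "IL-7",
    "IL-8",
    "IL-10",
    "IL-12p40",
    "IL-12p70",
    "IL-13",
    "IL-15",
    "IL-17A",
    "IP-10",
    "MCP-1",
    "MIG",
    "MIP-1a",
    "MIP-1b",
    "TNF-a",
    "HMGB1",
    "NO2+NO3",
)

MOUSE_PANEL = (
    "GM-CSF",
    "IFN-g",
    "IL-1a",
    "IL-1b",
    "IL-2",
    "IL-4",
    "IL-5",
    "IL-6",
    "IL-10",
    "IL-12p40",
    "IL-12p70",
    "IL-13",
    "IL-17",
    "IP-10",
    "KC",
    "MCP-1",
    "MIG",
    "MIP-1a",
    "TNF-a",
    "VEGF",
    "HMGB1",
    "NO2+NO3",
    "GDF-15",
)

assert len(HUMAN_PANEL) == 28
assert len(MOUSE_PANEL) == 23
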