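"""Published reference results for the packaged Venezuelan marsupial data.

These are the values reported in the original study of this data set: the
node-by-node segregation table for both classification modes, the group
memberships, and the ordination variance fractions.  They serve as the
comparison surface for :func:`chorotypes.pipeline.reproduce_reference` —
computed results are compared against them and any disagreement is listed,
never hidden.

Three of the published DW values (marked ``dw_inconsistent``) are not the
mean of their own published DW(A*A)/DW(B*B) components and none of the
published DW component sets is reproducible from integer zone counts
consistent with the published G statistics; they are carried here verbatim
and flagged as a reporting inconsistency of the source.
"""

from __future__ import annotations

__all__ = [
    "REFERENCE_SEGREGATION",
    "REFERENCE_OBUS",
    "REFERENCE_CHOROTYPES",
    "REFERENCE_RDA",
    "DW_INCONSISTENT_NODES",
]

# One entry per published segregation-table row.  Groups are given by member
# labels; "stars" columns are the published significance codes.
REFERENCE_SEGREGATION = [
    # --- Q-mode (regions) ---
    {"mode": "Q", "group_a": ["B2", "D6"],
     "group_b": ["B1", "B3", "C1", "D1", "D2", "D3", "D4", "D5"],
     "distance": 0.464, "dw_aa": -0.176, "dw_bb": 0.343, "dw": 0.172,
     "gw": 5.367, "gw_stars": "*", "ds": -0.116, "gs": 0.089, "gs_stars": "n.s."},
    {"mode": "Q", "group_a": ["B4", "B5", "C2", "D7"],
     "group_b": ["B1", "B2", "B3", "C1", "D1", "D2", "D3", "D4", "D5", "D6"],
     "distance": 0.592, "dw_aa": 0.640, "dw_bb": 0.384, "dw": 0.512,
     "gw": 31.000, "gw_stars": "***", "ds": 0.183, "gs": 8.109, "gs_stars": "**"},
    {"mode": "Q", "group_a": ["A2"],
     "group_b": ["B1", "B2", "B3", "B4", "B5", "C1", "C2",
                  "D1", "D2", "D3", "D4", "D5", "D6", "D7"],
     "distance": 1.000, "dw_aa": 0.000, "dw_bb": 0.157, "dw": 0.079,
     "gw": 4.936, "gw_stars": "*", "ds": 0.599, "gs": 43.482, "gs_stars": "***"},
    # --- R-mode (chorotypes) ---
    {"mode": "R",
     "group_a": ["Marmosa tyleriana", "Marmosops neblina",
                  "Marmosops pakaraimae", "Monodelphis reigi"],
     "group_b": ["Caluromys philander", "Monodelphis brevicaudata",
                  "Didelphis imperfecta", "Lutreolina crassicaudata"],
     "distance": 0.385, "dw_aa": 0.707, "dw_bb": 0.416, "dw": 0.562,
     "gw": 16.228, "gw_stars": "***", "ds": 0.000, "gs": 0.0, "gs_stars": "n.s."},
    {"mode": "R",
     "group_a": ["Chironectes minimus", "Didelphis marsupialis",
                  "Marmosa demerarae", "Marmosa murina"],
     "group_b": ["Caluromys trinitatis", "Gracilinanus marica", "Marmosa robinsoni",
                  "Marmosops fuscatus", "Monodelphis palliolata"],
     "distance": 0.432, "dw_aa": 0.640, "dw_bb": 0.515, "dw": 0.577,
     "gw": 19.048, "gw_stars": "***", "ds": 0.000, "gs": 0.0, "gs_stars": "n.s."},
    {"mode": "R",
     "group_a": ["Caluromys lanatus", "Metachirus nudicaudatus", "Philander mondolfii"],
     "group_b": ["Chironectes minimus", "Didelphis marsupialis", "Marmosa demerarae",
                  "Marmosa murina", "Caluromys trinitatis", "Gracilinanus marica",
                  "Marmosa robinsoni", "Marmosops fuscatus", "Monodelphis palliolata"],
     "distance": 0.521, "dw_aa": 0.227, "dw_bb": 0.221, "dw": 0.260,
     "gw": 4.249, "gw_stars": "*", "ds": -0.071, "gs": 0.0, "gs_stars": "n.s."},
    {"mode": "R",
     "group_a": ["Marmosa lepida", "Marmosops pinheiroi", "Philander andersoni"],
     "group_b": ["Marmosa tyleriana", "Marmosops neblina", "Marmosops pakaraimae",
                  "Monodelphis reigi", "Caluromys philander", "Monodelphis brevicaudata",
                  "Didelphis imperfecta", "Lutreolina crassicaudata"],
     "distance": 0.615, "dw_aa": 0.252, "dw_bb": -0.001, "dw": 0.277,
     "gw": 0.014, "gw_stars": "n.s.", "ds": 0.085, "gs": 17.030, "gs_stars": "***"},
    {"mode": "R",
     "group_a": ["Caenolestes fuliginosus", "Didelphis pernigra", "Gracilinanus dryas",
                  "Marmosa waterhousei", "Marmosops impavidus", "Monodelphis adusta"],
     "group_b": ["Caluromys lanatus", "Metachirus nudicaudatus", "Philander mondolfii",
                  "Chironectes minimus", "Didelphis marsupialis", "Marmosa demerarae",
                  "Marmosa murina", "Caluromys trinitatis", "Gracilinanus marica",
                  "Marmosa robinsoni", "Marmosops fuscatus", "Monodelphis palliolata"],
     "distance": 0.633, "dw_aa": 0.707, "dw_bb": 0.207, "dw": 0.457,
     "gw": 37.544, "gw_stars": "***", "ds": 0.082, "gs": 5.681, "gs_stars": "*"},
    {"mode": "R", "group_a": None, "group_b": None,  # V–VII vs VIII–XI (27 spp)
     "distance": 0.857, "dw_aa": 0.130, "dw_bb": 0.147, "dw": 0.139,
     "gw": 64.568, "gw_stars": "***", "ds": 0.488, "gs": 160.889, "gs_stars": "***"},
    {"mode": "R", "group_a": ["Philander deltae"], "group_b": None,
     "distance": 0.896, "dw_aa": 0.000, "dw_bb": -0.220, "dw": -0.110,
     "gw": 3.997, "gw_stars": "n.s.", "ds": 0.178, "gs": 12.738, "gs_stars": "***"},
    {"mode": "R", "group_a": ["Monodelphis species A"], "group_b": None,
     "distance": 0.928, "dw_aa": 0.000, "dw_bb": -0.247, "dw": -0.123,
     "gw": 3.778, "gw_stars": "n.s.", "ds": 0.235, "gs": 21.328, "gs_stars": "***"},
]

#: Published rows whose DW is not the mean of the published components.
DW_INCONSISTENT_NODES = (0.464, 0.521, 0.615)  # identified by distance

REFERENCE_OBUS = {
    "I": frozenset({"A2"}),
    "II": frozenset({"B4", "B5", "C2", "D7"}),
    "III": frozenset({"B2", "D6"}),
    "IV": frozenset({"B1", "B3", "C1", "D1", "D2", "D3", "D4", "D5"}),
}

REFERENCE_CHOROTYPES = {
    "I": frozenset({"Marmosa xerophila"}),
    "II": frozenset({"Marmosops cracens"}),
    "III": frozenset({"Monodelphis species A"}),
    "IV": frozenset({"Philander deltae"}),
    "V": frozenset({"Marmosa lepida", "Marmosops pinheiroi", "Philander andersoni"}),
    "VI": frozenset({"Marmosa tyleriana", "Marmosops neblina",
                     "Marmosops pakaraimae", "Monodelphis reigi"}),
    "VII": frozenset({"Caluromys philander", "Monodelphis brevicaudata",
                      "Didelphis imperfecta", "Lutreolina crassicaudata"}),
    "VIII": frozenset({"Caenolestes fuliginosus", "Didelphis pernigra",
                       "Gracilinanus dryas", "Marmosa waterhousei",
                       "Marmosops impavidus", "Monodelphis adusta"}),
    "IX": frozenset({"Caluromys lanatus", "Metachirus nudicaudatus",
                     "Philander mondolfii"}),
    "X": frozenset({"Chironectes minimus", "Didelphis marsupialis",
                    "Marmosa demerarae", "Marmosa murina"}),
    "XI": frozenset({"Caluromys trinitatis", "Gracilinanus marica",
                     "Marmosa robinsoni", "Marmosops fuscatus",
                     "Monodelphis palliolata"}),
}

#: Ordination variance fractions (percent) and axis-test significance.
REFERENCE_RDA = {
    "constrained_percent": 49.4,
    "axis1_percent": 25.8,
    "axis2_percent": 16.3,
    "axis1_p": "< 0.001",
    "axis2_p": 0.002,
    "n_permutations": 9999,
}
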