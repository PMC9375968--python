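"""Area records for the volitional-network roster.

Each record names an anatomical area, the Brainnetome sub-area label stems
belonging to it, its Brodmann label, its lobe group for connectogram
layout, and the movement process(es) it serves. Stems expand bilaterally
(``_l``/``_r``) in :func:`volnet.network_model.build_roster`; an area listed
under several processes (pre-SMA under Planning and Timing, the insula under
Motivation and Agency, A9m under Planning and Decision) merges into one node
per hemisphere with the union of processes. The full set yields 82 nodes.
"""

from __future__ import annotations

TABLE1_RECORDS: list[dict] = [
    # --- Motivation
    {
        "area_name": "Amygdala and nucleus accumbens",
        "sub_area_labels": ["mAmyg", "lAmyg", "NAC"],
        "brodmann_label": "N/A",
        "lobe_group": "SCN",
        "processes": ["MOTIVATION"],
    },
    {
        "area_name": "Orbitofrontal cortex",
        "sub_area_labels": ["A11l", "A11m"],
        "brodmann_label": "BA11",
        "lobe_group": "FRO",
        "processes": ["MOTIVATION"],
    },
    {
        "area_name": "Insular cortex",
        "sub_area_labels": ["G", "vla", "dla", "vId/vIg", "dIg", "dId"],
        "brodmann_label": "BA13/14/16",
        "lobe_group": "INS",
        "processes": ["MOTIVATION"],
    },
    # --- Modulation of Motivation
    {
        "area_name": "Posterior cingulate cortex",
        "sub_area_labels": ["A31"],
        "brodmann_label": "BA31",
        "lobe_group": "LIM",
        "processes": ["MOD_MOTIVATION"],
    },
    {
        "area_name": "Posterior cingulate cortex",
        "sub_area_labels": ["A23d", "A23v", "A23c"],
        "brodmann_label": "BA23",
        "lobe_group": "LIM",
        "processes": ["MOD_MOTIVATION"],
    },
    # --- Planning
    {
        "area_name": "Prefrontal cortex",
        "sub_area_labels": ["A9l", "A9m"],
        "brodmann_label": "BA9",
        "lobe_group": "FRO",
        "processes": ["PLANNING"],
    },
    {
        "area_name": "Prefrontal cortex",
        "sub_area_labels": ["A10m", "A10l"],
        "brodmann_label": "BA10",
        "lobe_group": "FRO",
        "processes": ["PLANNING"],
    },
    {
        "area_name": "Anterior cingulate cortex",
        "sub_area_labels": ["A24rv", "A24cd"],
        "brodmann_label": "BA24",
        "lobe_group": "LIM",
        "processes": ["PLANNING"],
    },
    {
        "area_name": "Anterior cingulate cortex",
        "sub_area_labels": ["A32p", "A32sg"],
        "brodmann_label": "BA32",
        "lobe_group": "LIM",
        "processes": ["PLANNING"],
    },
    {
        "area_name": "Anterior parietal cortex",
        "sub_area_labels": ["A40rd", "A40rv"],
        "brodmann_label": "BA40",
        "lobe_group": "PAR",
        "processes": ["PLANNING"],
    },
    {
        "area_name": "Pre-supplementary motor area",
        "sub_area_labels": ["A6dl", "A6m", "A6vl", "A6cdl", "A6cvl"],
        "brodmann_label": "BA6",
        "lobe_group": "FRO",
        "processes": ["PLANNING"],
    },
    # --- Timing
    {
        "area_name": "Pre-supplementary motor area",
        "sub_area_labels": ["A6dl", "A6m", "A6vl", "A6cdl", "A6cvl"],
        "brodmann_label": "BA6",
        "lobe_group": "FRO",
        "processes": ["TIMING"],
    },
    {
        "area_name": "Dorsolateral prefrontal cortex",
        "sub_area_labels": ["A9l"],
        "brodmann_label": "BA9",
        "lobe_group": "FRO",
        "processes": ["TIMING"],
    },
    {
        "area_name": "Dorsolateral prefrontal cortex",
        "sub_area_labels": ["A9/46d"],
        "brodmann_label": "BA9/46",
        "lobe_group": "FRO",
        "processes": ["TIMING"],
    },
    # --- Decision
    {
        "area_name": "Dorsal frontomedial cortex",
        "sub_area_labels": ["A9m"],
        "brodmann_label": "BA9",
        "lobe_group": "FRO",
        "processes": ["DECISION"],
    },
    # --- Execution
    {
        "area_name": "Primary motor cortex",
        "sub_area_labels": ["A4hf", "A4ul", "A4t", "A4tl", "A4ll"],
        "brodmann_label": "BA4",
        "lobe_group": "FRO",
        "processes": ["EXECUTION"],
    },
    # --- Agency
    {
        "area_name": "Insular cortex",
        "sub_area_labels": ["G", "vla", "dla", "vId/vIg", "dIg", "dId"],
        "brodmann_label": "BA13/14/16",
        "lobe_group": "INS",
        "processes": ["AGENCY"],
    },
    # --- Modulation of Agency
    {
        "area_name": "Inferior parietal cortex (angular gyrus / TPJ)",
        "sub_area_labels": ["A39c", "A39rd", "A39rv"],
        "brodmann_label": "BA39",
        "lobe_group": "PAR",
        "processes": ["MOD_AGENCY"],
    },
    {
        "area_name": "Extrastriate body area (MT/V5 cluster)",
        "sub_area_labels": ["V5_MT_plus"],
        "brodmann_label": "BA19",
        "lobe_group": "OCC",
        "processes": ["MOD_AGENCY"],
    },
    {
        "area_name": "Caudoposterior superior temporal sulcus",
        "sub_area_labels": ["cpSTS"],
        "brodmann_label": "BA22",
        "lobe_group": "TEM",
        "processes": ["MOD_AGENCY"],
    },
]
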