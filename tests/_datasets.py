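"""Small published reference data used as test inputs.

Dual-assay potencies (pIC50) of fifteen benzodiazepinone mGluR2
antagonists reported with both a radioligand-displacement endpoint (I)
and a cAMP functional endpoint (II).
"""

DUAL_ENDPOINT_PIC50 = {
    "2": (7.4685, 7.7696),
    "15c": (7.6990, 7.7959),
    "15m": (7.7447, 7.8861),
    "15q": (7.6990, 7.7696),
    "7o": (7.5086, 7.4437),
    "7z": (7.9586, 7.8539),
    "7ac": (7.5376, 7.1308),
    "8a": (7.9208, 7.7212),
    "8h": (8.3979, 7.9586),
    "8y": (7.5850, 7.5229),
    "8aa": (7.8861, 8.3010),
    "8ae": (8.3010, 8.0000),
    "8aj": (8.2218, 7.3010),
    "8ao": (8.6990, 8.3979),
    "8av": (8.3979, 8.6990),
}
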