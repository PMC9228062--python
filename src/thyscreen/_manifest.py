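"""Pinned descriptor manifests.

The modeling feature space is a fixed set of 119 RDKit 2-D physicochemical
descriptors.  The exact membership of "the RDKit 2-D descriptor set" drifts
across RDKit releases, so the list is frozen here under a version tag and the
tag is recorded in every model bundle; a model only scores matrices computed
under its own manifest.  Composite drug-likeness scores and fingerprint
densities introduced in recent RDKit releases are deliberately excluded.
"""

DESCRIPTOR_SETS: dict[str, list[str]] = {
    "rdkit2d-119-v1": [
        "MaxAbsEStateIndex", "MaxEStateIndex", "MinAbsEStateIndex",
        "MinEStateIndex", "MolWt", "HeavyAtomMolWt", "ExactMolWt",
        "NumValenceElectrons", "NumRadicalElectrons", "MaxPartialCharge",
        "MinPartialCharge", "MaxAbsPartialCharge", "MinAbsPartialCharge",
        "BCUT2D_MWHI", "BCUT2D_MWLOW", "BCUT2D_CHGHI", "BCUT2D_CHGLO",
        "BCUT2D_LOGPHI", "BCUT2D_LOGPLOW", "BCUT2D_MRHI", "BCUT2D_MRLOW",
        "BalabanJ", "BertzCT", "Chi0", "Chi0n", "Chi0v", "Chi1", "Chi1n",
        "Chi1v", "Chi2n", "Chi2v", "Chi3n", "Chi3v", "Chi4n", "Chi4v",
        "HallKierAlpha", "Ipc", "Kappa1", "Kappa2", "Kappa3", "LabuteASA",
        "PEOE_VSA1", "PEOE_VSA10", "PEOE_VSA11", "PEOE_VSA12", "PEOE_VSA13",
        "PEOE_VSA14", "PEOE_VSA2", "PEOE_VSA3", "PEOE_VSA4", "PEOE_VSA5",
        "PEOE_VSA6", "PEOE_VSA7", "PEOE_VSA8", "PEOE_VSA9", "SMR_VSA1",
        "SMR_VSA10", "SMR_VSA2", "SMR_VSA3", "SMR_VSA4", "SMR_VSA5",
        "SMR_VSA6", "SMR_VSA7", "SMR_VSA8", "SMR_VSA9", "SlogP_VSA1",
        "SlogP_VSA10", "SlogP_VSA11", "SlogP_VSA12", "SlogP_VSA2",
        "SlogP_VSA3", "SlogP_VSA4", "SlogP_VSA5", "SlogP_VSA6", "SlogP_VSA7",
        "SlogP_VSA8", "SlogP_VSA9", "TPSA", "EState_VSA1", "EState_VSA10",
        "EState_VSA11", "EState_VSA2", "EState_VSA3", "EState_VSA4",
        "EState_VSA5", "EState_VSA6", "EState_VSA7", "EState_VSA8",
        "EState_VSA9", "VSA_EState1", "VSA_EState10", "VSA_EState2",
        "VSA_EState3", "VSA_EState4", "VSA_EState5", "VSA_EState6",
        "VSA_EState7", "VSA_EState8", "VSA_EState9", "FractionCSP3",
        "HeavyAtomCount", "NHOHCount", "NOCount", "NumAliphaticCarbocycles",
        "NumAliphaticHeterocycles", "NumAliphaticRings",
        "NumAromaticCarbocycles", "NumAromaticHeterocycles",
        "NumAromaticRings", "NumHAcceptors", "NumHDonors", "NumHeteroatoms",
        "NumRotatableBonds", "NumSaturatedCarbocycles",
        "NumSaturatedHeterocycles", "NumSaturatedRings", "RingCount",
        "MolLogP", "MolMR",
    ],
}

DEFAULT_DESCRIPTOR_SET = "rdkit2d-119-v1"
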