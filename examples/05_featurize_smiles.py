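"""Turn SMILES strings into the three built-in descriptor tables."""

from fntscreen import CompoundRecord, featurize

records = [
    CompoundRecord(id="ethanol", smiles="CCO"),
    CompoundRecord(id="aspirin", smiles="CC(=O)Oc1ccccc1C(=O)O"),
    CompoundRecord(id="caffeine", smiles="Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
]

for descriptor in ("maccs", "ecfp6", "rdkit2d"):
    fm = featurize(records, descriptor)
    print(f"{descriptor:8s} -> {fm.matrix.shape[0]} compounds x {fm.n_features} features")
# MACCS is always 166 structural keys and ECFP6 2048 circular-fingerprint
# bits; the RDKit 2D panel width depends on the installed RDKit version.
# Precomputed tables (e.g. 1,613-column macrocycle descriptors) load via
# fntscreen.load_feature_csv.
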