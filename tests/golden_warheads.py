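"""Golden-molecule suite: for each warhead, positive matches and
near-miss negatives (e.g. internal vs terminal alkyne, amide vs
acrylamide, acid chloride vs alpha-haloketone)."""

GOLDEN = {
    "aldehyde": (
        ["O=Cc1ccccc1", "CCCC=O"],
        ["CC(C)=O", "NC=O"],
    ),
    "alpha_haloketone": (
        ["CC(=O)CCl", "O=C(CBr)c1ccccc1"],
        ["CC(=O)Cl", "CC(=O)CCCl"],
    ),
    "acrylate": (
        ["C=CC(=O)OC", "CC(=C)C(=O)OCC"],
        ["C=CC(=O)O", "CCC(=O)OC"],
    ),
    "alkynyl_benzoate": (
        ["C#CCOC(=O)c1ccccc1", "CC#CCOC(=O)c1ccccc1"],
        ["C#CCOC(C)=O", "OCC#C"],
    ),
    "boronic_acid": (
        ["OB(O)c1ccccc1", "CB(O)O"],
        ["CB(OC)OC", "OB(O)O"],
    ),
    "cyanoacrylamide": (
        ["N#CC(=C)C(N)=O", "N#CC(=CC)C(=O)Nc1ccccc1"],
        ["C=CC(N)=O", "N#CC(=C)C(=O)OC"],
    ),
    "cyanamide": (
        ["CN(C)C#N", "N#CN1CCCC1"],
        ["CC#N", "NC(=O)C#N"],
    ),
    "epoxide": (
        ["CC1CO1", "c1ccccc1C1CO1"],
        ["C1CCO1", "C1CCCO1"],
    ),
    "reactive_ester": (
        ["CC(=O)Oc1ccc([N+](=O)[O-])cc1", "CC(=O)ON1C(=O)CCC1=O"],
        ["CC(=O)Oc1ccccc1", "CC(=O)OC"],
    ),
    "sulfonyl_fluoride": (
        ["CS(=O)(=O)F", "O=S(=O)(F)c1ccccc1"],
        ["CS(=O)(=O)Cl", "CS(N)(=O)=O"],
    ),
    "terminal_alkyne": (
        ["C#Cc1ccccc1", "CCCCC#C"],
        ["CC#CC", "CC#N"],
    ),
    "vinyl_sulfone": (
        ["C=CS(=O)(=O)c1ccccc1", "C=CS(C)(=O)=O"],
        ["CCS(C)(=O)=O", "C=CS(C)=O"],
    ),
    "acrylamide": (
        ["C=CC(N)=O", "C=CC(=O)Nc1ccccc1"],
        ["CCC(N)=O", "CC(=O)N"],
    ),
    "heterocyclic_urea": (
        ["NC(=O)Nc1ccccn1", "NC(=O)Nc1nccs1"],
        ["NC(=O)Nc1ccccc1", "CNC(=O)NC"],
    ),
}
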