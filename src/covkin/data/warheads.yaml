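# Default electrophilic-warhead substructure library.
#
# Each entry: name -> {smarts, specificity_rank}.  Lower rank = more
# specific; an embedding of a less specific pattern is suppressed when
# it is fully contained in an embedding of a more specific one (e.g.
# the acrylamide inside a cyanoacrylamide).
#
# The patterns are authored from the depicted warhead structures; a
# user config may override or extend any entry.
aldehyde:
  # aliphatic/aromatic aldehyde on carbon; excludes formamide-type C(=O)N
  smarts: "[CX3H1](=O)[#6]"
  specificity_rank: 5
alpha_haloketone:
  # ketone with halogen on the alpha sp3 carbon; excludes acid halides
  smarts: "[#6][CX3](=O)[CX4!H0][F,Cl,Br,I]"
  specificity_rank: 5
acrylate:
  # alpha,beta-unsaturated ester (acrylic ester), O-alkyl/aryl
  smarts: "[CX3]=[CX3][CX3](=O)[OX2][#6]"
  specificity_rank: 1
alkynyl_benzoate:
  # benzoate ester of a propargylic alcohol (alkyne one sp3 carbon from O)
  smarts: "C#C[CX4][OX2]C(=O)c1ccccc1"
  specificity_rank: 1
boronic_acid:
  smarts: "[#6][BX3]([OX2H])[OX2H]"
  specificity_rank: 5
cyanoacrylamide:
  # alpha-cyano acrylamide
  smarts: "[NX1]#[CX2][CX3](=[CX3])[CX3](=O)[NX3]"
  specificity_rank: 1
cyanamide:
  # N-C#N
  smarts: "[NX3][CX2]#[NX1]"
  specificity_rank: 5
epoxide:
  smarts: "[CX4]1[OX2][CX4]1"
  specificity_rank: 5
reactive_ester:
  # activated ester: nitrophenyl, pentafluorophenyl or O-N (NHS-type)
  smarts: "[CX3](=O)[OX2;$(Oc1ccc([N+](=O)[O-])cc1),$(Oc1c(F)c(F)c(F)c(F)c1F),$(O[NX3])]"
  specificity_rank: 2
sulfonyl_fluoride:
  smarts: "[#6][SX4](=O)(=O)F"
  specificity_rank: 5
terminal_alkyne:
  smarts: "C#[CX2H1]"
  specificity_rank: 2
vinyl_sulfone:
  smarts: "[CX3]=[CX3][SX4](=O)(=O)[#6]"
  specificity_rank: 5
acrylamide:
  smarts: "[CX3]=[CX3][CX3](=O)[NX3]"
  specificity_rank: 2
heterocyclic_urea:
  # urea with one N on an aromatic heterocycle (aromatic n/o/s reachable
  # through aromatic bonds from the attachment carbon)
  smarts: "[NX3]C(=O)[NX3][c;$(c[n,o,s]),$(c:c:[n,o,s]),$(c:c:c:[n,o,s])]"
  specificity_rank: 5
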