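{
  "comment": "Aquatic-toxicity structural alerts. SMARTS written independently from each alert's chemical name; the positive/negative control pair defines each pattern's contract.",
  "alerts": [
    {
      "alert_id": "TA662",
      "name": "aliphatic secondary and tertiary amines",
      "smarts": ["[NX3;H1,H0;+0;!$([NX3]C=O);!$([NX3][a]);!$([NX3]~[OX1]);!$([NX3]=*)]"],
      "positive_control": "CCNCC",
      "negative_control": "CCN",
      "note": "excludes primary amines, amides, anilines, N-oxides"
    },
    {
      "alert_id": "TA665",
      "name": "primary alkyl amines",
      "smarts": ["[NX3;H2;+0;!$(N[a]);!$(NC=O)][CX4]"],
      "positive_control": "CCCN",
      "negative_control": "Nc1ccccc1",
      "note": "NH2 on sp3 carbon; anilines and amides excluded"
    },
    {
      "alert_id": "TA642",
      "name": "ammonium (NH3+) groups",
      "smarts": ["[NX4+;H3]"],
      "positive_control": "CC[NH3+]",
      "negative_control": "CCN",
      "note": "protonated primary ammonium"
    },
    {
      "alert_id": "TA628",
      "name": "beta-unsaturated nitro compounds",
      "smarts": ["[CX3]=[CX3][$([NX3+](=O)[O-]),$([NX3](=O)=O)]"],
      "positive_control": "C=C[N+](=O)[O-]",
      "negative_control": "CC[N+](=O)[O-]",
      "note": "nitro conjugated to a C=C double bond"
    },
    {
      "alert_id": "TA11521",
      "name": "4-nitrobenzene",
      "smarts": ["c1ccc([NX3+](=O)[O-])cc1", "c1ccc([NX3](=O)=O)cc1"],
      "positive_control": "O=[N+]([O-])c1ccccc1",
      "negative_control": "O=[N+]([O-])C1CCCCC1",
      "note": "nitro group on a benzenoid aromatic ring"
    },
    {
      "alert_id": "TA667",
      "name": "activated alkenes and alkynes",
      "smarts": [
        "[CX3]=[CX3][$([CX3]=[OX1]),$([CX2]#[NX1]),$([NX3+](=O)[O-]),$([SX4](=O)=O)]",
        "[CX2]#[CX2][$([CX3]=[OX1]),$([CX2]#[NX1]),$([NX3+](=O)[O-]),$([SX4](=O)=O)]"
      ],
      "positive_control": "C=CC=O",
      "negative_control": "CC=CC",
      "note": "Michael-acceptor C=C / C#C next to an electron-withdrawing group"
    },
    {
      "alert_id": "TA617",
      "name": "phosphoric acid ester",
      "smarts": ["[PX4](=[OX1])[OX2][#6]"],
      "positive_control": "COP(=O)(OC)OC",
      "negative_control": "CP(=O)(O)O",
      "note": "P(=O) with at least one O-C ester linkage"
    },
    {
      "alert_id": "TA626",
      "name": "alpha,beta-unsaturated nitriles",
      "smarts": ["[CX3]=[CX3][CX2]#[NX1]"],
      "positive_control": "C=CC#N",
      "negative_control": "CCC#N",
      "note": "nitrile conjugated to a C=C double bond"
    },
    {
      "alert_id": "TA631",
      "name": "alpha,beta-unsaturated carboxylic acid",
      "smarts": ["[CX3]=[CX3][CX3](=O)[OX2H1]"],
      "positive_control": "C=CC(=O)O",
      "negative_control": "CCC(=O)O",
      "note": "acrylic-acid motif"
    },
    {
      "alert_id": "TA1181",
      "name": "carboxylic acid secondary amides",
      "smarts": ["[CX3](=[OX1])[NX3;H1][#6]"],
      "positive_control": "CC(=O)NC",
      "negative_control": "CC(=O)N",
      "note": "N-monosubstituted amide"
    },
    {
      "alert_id": "TA1176",
      "name": "carboxylic acids",
      "smarts": ["[CX3](=O)[OX2H1]"],
      "positive_control": "CC(=O)O",
      "negative_control": "COC(C)=O",
      "note": "free COOH; esters do not fire"
    },
    {
      "alert_id": "TA659",
      "name": "aliphatic alcohols",
      "smarts": ["[CX4][OX2H1]"],
      "positive_control": "CCO",
      "negative_control": "Oc1ccccc1",
      "note": "OH on sp3 carbon; phenols excluded"
    },
    {
      "alert_id": "TA638",
      "name": "halogenated benzylic group",
      "smarts": ["[F,Cl,Br,I][CX4][c]"],
      "positive_control": "ClCc1ccccc1",
      "negative_control": "Clc1ccccc1",
      "note": "halogen on a benzylic sp3 carbon"
    },
    {
      "alert_id": "TA634",
      "name": "halide groups (F)",
      "smarts": ["[FX1]"],
      "positive_control": "CCF",
      "negative_control": "CCCl",
      "note": "covalent fluorine"
    }
  ]
}
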