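"""Vendored grouping tables for the CTD and Conjoint Triad encodings.

CTD: 13 physicochemical properties, each partitioning the 20 residues into
three groups (hydrophobicity under seven scales, normalized van der Waals
volume, polarity, polarizability, charge, secondary-structure propensity,
solvent accessibility), following the iLearnPlus/iFeature convention.

CTriad: the 7 conjoint classes grouping residues by dipole and side-chain
volume.
"""

CTD_PROPERTIES = (
    "hydrophobicity_PRAM900101",
    "hydrophobicity_ARGP820101",
    "hydrophobicity_ZIMJ680101",
    "hydrophobicity_PONP930101",
    "hydrophobicity_CASG920101",
    "hydrophobicity_ENGD860101",
    "hydrophobicity_FASG890101",
    "normwaalsvolume",
    "polarity",
    "polarizability",
    "charge",
    "secondarystruct",
    "solventaccess",
)

CTD_GROUPS = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

CTRIAD_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")
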