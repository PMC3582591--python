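"""Built-in hg19 centromere coordinates.

Midpoints of the acen cytoband gap per chromosome (UCSC hg19 cytoBand
track), rounded to the nearest base.  Probes at positions at or below the
centromere are assigned to the p arm.  Users working on other assemblies
supply their own two-column ``chrom<TAB>centromere_pos`` file.
"""

HG19_CENTROMERES: dict[str, int] = {
    "1": 123035434,
    "2": 93826171,
    "3": 92004854,
    "4": 51160117,
    "5": 47905641,
    "6": 60330166,
    "7": 59554331,
    "8": 45338887,
    "9": 48867679,
    "10": 40754935,
    "11": 53144205,
    "12": 36356694,
    "13": 17500000,
    "14": 17500000,
    "15": 18500000,
    "16": 36835801,
    "17": 23763006,
    "18": 16960898,
    "19": 26181782,
    "20": 27869569,
    "21": 12788129,
    "22": 14500000,
    "X": 60132012,
    "Y": 11604553,
}
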