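[
  {"gene": "AR",      "chrom": "X",  "start": 66765159,  "end": 66765228,  "motif": "CAG",          "pathogenic_min": 38},
  {"gene": "ATN1",    "chrom": "12", "start": 7045879,   "end": 7045936,   "motif": "CAG",          "pathogenic_min": 48},
  {"gene": "ATXN1",   "chrom": "6",  "start": 16327865,  "end": 16327955,  "motif": "CTG",          "pathogenic_min": 39},
  {"gene": "ATXN10",  "chrom": "22", "start": 46191235,  "end": 46191304,  "motif": "ATTCT",        "pathogenic_min": 800},
  {"gene": "ATXN2",   "chrom": "12", "start": 112036754, "end": 112036823, "motif": "GCT",          "pathogenic_min": 33},
  {"gene": "ATXN3",   "chrom": "14", "start": 92537355,  "end": 92537396,  "motif": "CTG",          "pathogenic_min": 60},
  {"gene": "ATXN7",   "chrom": "3",  "start": 63898361,  "end": 63898391,  "motif": "CAG",          "pathogenic_min": 37},
  {"gene": "C9ORF72", "chrom": "9",  "start": 27573483,  "end": 27573544,  "motif": "GGCCCC",       "pathogenic_min": 31},
  {"gene": "CACNA1A", "chrom": "19", "start": 13318673,  "end": 13318712,  "motif": "CTG",          "pathogenic_min": 20},
  {"gene": "CBL",     "chrom": "11", "start": 119076999, "end": 119077032, "motif": "CGG",          "pathogenic_min": 100},
  {"gene": "CSTB",    "chrom": "21", "start": 45196324,  "end": 45196360,  "motif": "CGCGGGGCGGGG", "pathogenic_min": 30},
  {"gene": "DMPK",    "chrom": "19", "start": 46273463,  "end": 46273524,  "motif": "CAG",          "pathogenic_min": 50},
  {"gene": "FMR1",    "chrom": "X",  "start": 146993569, "end": 146993628, "motif": "CGG",          "pathogenic_min": 200},
  {"gene": "FXN",     "chrom": "9",  "start": 71652201,  "end": 71652220,  "motif": "GAA",          "pathogenic_min": 66},
  {"gene": "HTT",     "chrom": "4",  "start": 3076604,   "end": 3076660,   "motif": "CAG",          "pathogenic_min": 36},
  {"gene": "JPH3",    "chrom": "16", "start": 87637889,  "end": 87637935,  "motif": "CTG",          "pathogenic_min": 40},
  {"gene": "PPP2R2B", "chrom": "5",  "start": 146258291, "end": 146258322, "motif": "GCT",          "pathogenic_min": 43}
]
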