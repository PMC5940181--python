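"""Published benchmark values used as *inputs* to the comparison framework.

These are printed results from a large-scale DDI link-prediction benchmark
over five public interaction databases; the package's statistical machinery
(F1 consistency, overlap conventions, Friedman/Nemenyi) is exercised
against them as fixed numeric fixtures.
"""

CLASSIFIERS = ("tree", "knn", "svm_linear", "random_forest", "gbm")
NETWORKS = ("DrugBank", "KEGG", "NDF-RT", "SemMedDB", "Twosides")

# AUPR of the five classifier families on the five networks (training data)
AUPR_TRAIN = [
    [0.64, 0.89, 0.78, 1.00, 0.82],
    [0.42, 0.67, 0.45, 1.00, 0.60],
    [0.25, 0.37, 0.20, 0.91, 0.53],
    [0.36, 0.59, 0.48, 0.97, 0.54],
    [0.86, 0.95, 0.94, 1.00, 0.96],
]

# AUPR on held-out test data (note the RF/GBM tie at 0.93 on Twosides)
AUPR_TEST = [
    [0.63, 0.81, 0.78, 0.92, 0.82],
    [0.42, 0.51, 0.47, 0.69, 0.55],
    [0.20, 0.17, 0.21, 0.36, 0.27],
    [0.36, 0.45, 0.50, 0.55, 0.53],
    [0.80, 0.90, 0.92, 0.93, 0.93],
]

# (precision, recall, f1) triples as printed (2 decimals)
PRF_UNSUPERVISED = [
    ("DrugBank", "train", 0.63, 0.68, 0.65),
    ("DrugBank", "test", 0.63, 0.68, 0.65),
    ("KEGG", "train", 0.28, 0.63, 0.38),
    ("KEGG", "test", 0.28, 0.64, 0.39),
    ("NDF-RT", "train", 0.09, 0.58, 0.15),
    ("NDF-RT", "test", 0.08, 0.56, 0.14),
    ("SemMedDB", "train", 0.16, 0.80, 0.27),
    ("SemMedDB", "test", 0.17, 0.83, 0.28),
    ("Twosides", "train", 0.96, 0.30, 0.46),
    ("Twosides", "test", 0.96, 0.30, 0.45),
]

PRF_SUPERVISED_TRAIN = [
    ("DrugBank", "tree", 0.84, 0.56, 0.67),
    ("DrugBank", "knn", 0.86, 0.70, 0.77),
    ("DrugBank", "svm_linear", 0.83, 0.59, 0.69),
    ("DrugBank", "random_forest", 0.84, 0.56, 0.67),
    ("DrugBank", "gbm", 0.83, 0.65, 0.73),
    ("KEGG", "tree", 0.68, 0.34, 0.46),
    ("KEGG", "knn", 0.76, 0.40, 0.53),
    ("KEGG", "svm_linear", 0.70, 0.21, 0.33),
    ("KEGG", "random_forest", 0.68, 0.34, 0.46),
    ("KEGG", "gbm", 0.71, 0.42, 0.53),
    ("NDF-RT", "tree", 0.77, 0.17, 0.28),
    ("NDF-RT", "knn", 0.59, 0.05, 0.10),
    ("NDF-RT", "svm_linear", 0.58, 0.09, 0.15),
    ("NDF-RT", "random_forest", 0.77, 0.17, 0.28),
    ("NDF-RT", "gbm", 0.91, 0.28, 0.43),
    ("SemMedDB", "tree", 0.76, 0.24, 0.36),
    ("SemMedDB", "knn", 0.74, 0.31, 0.43),
    ("SemMedDB", "svm_linear", 0.70, 0.27, 0.39),
    ("SemMedDB", "random_forest", 0.76, 0.24, 0.36),
    ("SemMedDB", "gbm", 0.76, 0.32, 0.46),
    ("Twosides", "tree", 0.88, 0.84, 0.86),
    ("Twosides", "knn", 0.91, 0.81, 0.86),
    ("Twosides", "svm_linear", 0.90, 0.81, 0.85),
    ("Twosides", "random_forest", 0.88, 0.84, 0.86),
    ("Twosides", "gbm", 0.92, 0.87, 0.89),
]

PRF_SUPERVISED_TEST = [
    ("DrugBank", "tree", 0.83, 0.55, 0.66),
    ("DrugBank", "knn", 0.83, 0.66, 0.74),
    ("DrugBank", "svm_linear", 0.83, 0.58, 0.69),
    ("DrugBank", "random_forest", 0.83, 0.55, 0.66),
    ("DrugBank", "gbm", 0.83, 0.65, 0.73),
    ("KEGG", "tree", 0.66, 0.32, 0.43),
    ("KEGG", "knn", 0.68, 0.35, 0.46),
    ("KEGG", "svm_linear", 0.72, 0.21, 0.33),
    ("KEGG", "random_forest", 0.66, 0.32, 0.43),
    ("KEGG", "gbm", 0.67, 0.37, 0.48),
    ("NDF-RT", "tree", 0.60, 0.12, 0.20),
    ("NDF-RT", "knn", 0.25, 0.03, 0.06),
    ("NDF-RT", "svm_linear", 0.56, 0.07, 0.13),
    ("NDF-RT", "random_forest", 0.60, 0.12, 0.20),
    ("NDF-RT", "gbm", 0.63, 0.15, 0.24),
    ("SemMedDB", "tree", 0.73, 0.25, 0.38),
    ("SemMedDB", "knn", 0.68, 0.30, 0.42),
    ("SemMedDB", "svm_linear", 0.69, 0.29, 0.41),
    ("SemMedDB", "random_forest", 0.73, 0.25, 0.38),
    ("SemMedDB", "gbm", 0.68, 0.31, 0.43),
    ("Twosides", "tree", 0.83, 0.82, 0.82),
    ("Twosides", "knn", 0.85, 0.77, 0.81),
    ("Twosides", "svm_linear", 0.86, 0.80, 0.83),
    ("Twosides", "random_forest", 0.83, 0.82, 0.82),
    ("Twosides", "gbm", 0.86, 0.83, 0.85),
]

# DrugBank descriptive row: nodes, listed interaction count, printed mean degree
DRUGBANK_NODES = 2551
DRUGBANK_INTERACTIONS = 577712
DRUGBANK_AVG_DEGREE = 452.93

# Edge overlaps: shared(DrugBank, KEGG), undirected edge counts, printed proportion
SHARED_DRUGBANK_KEGG = 11961
EDGES_DRUGBANK = 296656
EDGES_KEGG = 33474
OVERLAP_DRUGBANK_KEGG = 0.36

FRIEDMAN_CHI2_TRAIN = 18.4
FRIEDMAN_CHI2_TEST = 17.72
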