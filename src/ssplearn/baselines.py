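"""Minimal baseline harness: classical classifiers over handcrafted encodings.

Feeds a fixed-length encoding (AAC/CTD*/CTriad) of each peptide to a standard
scikit-learn classifier, so the "learned representation vs handcrafted
features" comparison can be run in-package on any dataset.  Encodings are fed
raw (no scaling), which is documented behavior.
"""

from __future__ import annotations

from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .encodings import encode_dataset
from .io import PeptideDataset
from .metrics import MetricReport, evaluate

_CLASSIFIERS = {
    "logreg": lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
    "rf": lambda seed: RandomForestClassifier(n_estimators=200, random_state=seed),
    "svm": lambda seed: SVC(random_state=seed),
    "nb": lambda seed: GaussianNB(),
}


def evaluate_encoding_baseline(scheme: str, train: PeptideDataset,
                               test: PeptideDataset, classifier: str = "logreg",
                               seed: int = 0) -> MetricReport:
    """Fit ``classifier`` on ``scheme`` features of ``train``; report on ``test``."""
    if classifier not in _CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}; choose from {sorted(_CLASSIFIERS)}")
    X_train = encode_dataset(train, scheme).values
    X_test = encode_dataset(test, scheme).values
    clf = _CLASSIFIERS[classifier](seed)
    clf.fit(X_train, train.labels())
    preds = clf.predict(X_test)
    return evaluate(test.labels(), preds)
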