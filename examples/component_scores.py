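"""Component predictors on a hand-sized fixture.

Three annotated training proteins; one query with two homology hits.  The
naive prior ignores the query entirely; the homology vote weights each
hit's annotations by its bitscore.
"""

from goranker import (
    AnnotationSet,
    Hit,
    HitTable,
    fit_naive,
    predict_blast_knn,
    predict_naive,
)

train = AnnotationSet({"S1": {"GO:0000002", "GO:0000003"},
                       "S2": {"GO:0000002"},
                       "S3": {"GO:0000004"}})

priors = fit_naive(train)
print("naive priors:", {t: round(p, 3) for t, p in priors.items()})
print("every query gets the same row:", predict_naive(priors, ["Q"]).row("Q"))

hits = HitTable.from_hits([
    Hit(query="Q", subject="S1", identity=0.82, bitscore=60.0),
    Hit(query="Q", subject="S3", identity=0.55, bitscore=40.0),
])
votes = predict_blast_knn(hits, train)
print("homology vote for Q:", {t: round(s, 2) for t, s in votes.row("Q").items()})
print(
    "\nGO:0000002/3 get 60/(60+40) = 0.6 (only the first hit carries them);"
    "\nGO:0000004 gets 0.4 from the weaker hit."
)
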