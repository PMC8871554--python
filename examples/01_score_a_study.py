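"""Score a single hand-built study against the shipped TRIPOD checklist.

Builds a complete consensus rating for a development-only study that meets
every applicable requirement except the title item and the blinding
subitems, then prints the per-component numerator/denominator and overall
adherence score.
"""

from tripod_adherence import (
    RatingSet,
    Response,
    StudyRecord,
    StudyType,
    load_tripod,
    scoreable_components,
    study_score,
)

defn = load_tripod()
study = StudyRecord("example-1", StudyType.DEVELOPMENT, 2018, "Dermatology", 7.2)

failed = {"1", "6b", "7b"}  # title, outcome blinding, predictor blinding
responses = {}
for comp in scoreable_components(defn, StudyType.DEVELOPMENT) + [defn.component("21")]:
    for i, elem in enumerate(comp.elements):
        if comp.component_id in failed and i == 0:
            responses[(comp.component_id, elem.element_id)] = Response.NO
        else:
            responses[(comp.component_id, elem.element_id)] = Response.YES

consensus = RatingSet("example-1", "consensus", responses)
result = study_score(consensus, study, defn)

print(f"adhered components : {result.numerator}")
print(f"applicable         : {result.denominator}")
print(
    f"overall score      : {result.numerator}/{result.denominator} "
    f"= {result.score_pct:.1f}%"
)
print()
print("Three failed components out of 30 applicable ones give 27/30 = 90%;")
print("item 21 is rated but never counted, and the six validation-only")
print("components are outside the denominator for a development study.")
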