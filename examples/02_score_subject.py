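"""Score a subject's CT series for cerebral edema.

Renders a short phantom series, segments every slice, averages the
per-slice HU distributions and computes the Cerebral Edema Score
(CES = % of intracranial pixels with HU 17-24) and the mortality variant
(mCES = HU 19-23), then classifies against the reference cutoffs
(16.03 / 16.29 / 15.27 %).
"""

from ctdens import PhantomSpec, make_series, score_subject, subject_distribution

series, _ = make_series(PhantomSpec(seed=7), n_slices=4)
dist = subject_distribution(series)
score = score_subject(dist, subject_id=series.subject_id)

print(f"subject {score.subject_id}: n={dist.n_images} usable slices, "
      f"{dist.n_pixels} intracranial pixels")
print(f"CES  (HU 17-24) = {score.ces:6.2f} %  -> severity: {score.verdict_severity}")
print(f"                               -> delayed-edema risk: {score.verdict_delayed_risk}")
print(f"mCES (HU 19-23) = {score.mces:6.2f} %  -> mortality risk: {score.verdict_mortality_risk}")
print("A CES at or above 16.03 % flags severe edema; this intact phantom's "
      "tissue mixture peaks at HU 29, so its band mass sits near the mild median.")
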