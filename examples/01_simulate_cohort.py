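"""Simulate a small longitudinal screening cohort and inspect its structure.

The simulator draws per-patient risk factors, a discrete annual hazard
(logistic in the risk factors plus a latent frailty), roughly annual exams,
independent censoring, and four-view 16-bit mammograms in which a Gaussian
lesion grows on the future event side as the diagnosis approaches.
"""

from mammorisk import SimConfig, simulate_cohort, make_target_samples

config = SimConfig(n_patients=40, seed=1)
timelines, truth = simulate_cohort(config)

n_events = sum(tl.has_event for tl in timelines)
n_samples = sum(len(make_target_samples(tl)) for tl in timelines)
print(f"patients: {len(timelines)}, diagnosed during follow-up: {n_events}")
print(f"eligible target exams (>=1y follow-up or diagnosis): {n_samples}")

tl = next(t for t in timelines if t.has_event)
pt = truth.patients[tl.patient_id]
print(f"\nexample case {tl.patient_id}: {len(tl.exams)} exams, "
      f"true hazard {pt.hazard:.3f}/yr, diagnosis on the {tl.diagnosis_laterality} "
      f"side {pt.event_time_years:.1f}y after entry")
for k, exam in enumerate(tl.exams):
    brightest = max(int(img.max()) for img in exam.images.values())
    print(f"  exam {k} on {exam.exam_date}: BI-RADS {exam.birads}, "
          f"max pixel {brightest} (lesion brightens as diagnosis approaches)")
# The per-exam max pixel rises toward the diagnosis because the planted
# lesion's radius and contrast grow linearly within the 4-year horizon.
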