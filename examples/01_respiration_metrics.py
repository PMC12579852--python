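"""Compute breath-by-breath respiration metrics for one surface sequence.

A surface sequence is annotated as a series of (start, end) blow intervals.
Inhalation duration is half the blow duration; the sequence-level metrics
summarize how much air the whale moved and how fast it accumulated it.
"""

from whaleresp import BreathEvent, summarize_sequence

breaths = [BreathEvent("whale-01", "seq-01", s, e)
           for s, e in [(0.0, 2.0), (20.0, 22.0), (45.0, 47.0)]]

m = summarize_sequence(breaths)
print(f"breath count:            {m.breath_count}")
print(f"sequence duration:       {m.sequence_duration_s:.1f} s")
print(f"total inhalation:        {m.total_inhalation_s:.2f} s")
print(f"mean inter-breath gap:   {m.mean_ibi_s:.2f} s")
print(f"accumulation rate:       {m.accumulation_rate:.5f} s/s")

# The accumulation rate is the OLS slope of cumulative inhalation time
# against time since the first breath: ~0.044 s of inhalation per second at
# the surface, a proxy for how quickly this whale is recovering oxygen.
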