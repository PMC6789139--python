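"""Light-evoked EPSC analysis: averaging, peak detection, drug block.

Simulates whole-cell recordings (10 sweeps per cell, EPSCs planted in half
the cells at ~70 pA), classifies responders against the 10 pA criterion and
runs the paired CNQX-block comparison on the responding cells.
"""

from raphequant import ephys, synth

spec = synth.SweepSpec(n_cells=30, p_responder=0.5, amp_pa=(70.0, 10.0),
                       block_factor=0.05, trace_dur_s=0.3, seed=3)
sweepsets, truth = synth.make_sweeps(spec)

pre = [ephys.analyze_sweepset(s) for s in sweepsets if s.condition == "baseline"]
pct, n_resp, n = ephys.responder_fraction(pre)
print(f"responders: {n_resp}/{n} cells ({pct:.1f}%) exceed the 10 pA criterion "
      f"(planted: {int(truth.epsc.responder.sum())})")

resp_ids = {r.cell_id for r in pre if r.responder}
pre_r = [r for r in pre if r.cell_id in resp_ids]
post_r = [ephys.analyze_sweepset(s) for s in sweepsets
          if s.condition == "post" and s.cell_id in resp_ids]
blk = ephys.drug_block(pre_r, post_r)
print(f"baseline: {blk.pre_mean_pa:.1f} +/- {blk.pre_sem_pa:.1f} pA; "
      f"after block: {blk.post_mean_pa:.1f} +/- {blk.post_sem_pa:.1f} pA "
      f"(n = {len(blk.cell_ids)} cells)")
print(f"paired t-test: t({blk.test.df:.0f}) = {blk.test.statistic:.3f}, "
      f"p = {blk.test.p:.4f} {blk.test.stars}")
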