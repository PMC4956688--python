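"""Channel-by-time searchlight on planar gradiometer data.

Crosses a sensor-space neighborhood (combined gradiometers over planar
pairs) with a temporal interval neighborhood, then runs cross-validated
classification in every channel/time window.  The output has one accuracy
per (combined channel, time point) — 9 x 5 = 45 features for the toy
layout — and can be exported as a TSV table.
"""

import numpy as np

import mvlight as mv

ds = mv.make_toy_meeg(effect_size=1.5, seed=1)
layout = mv.load_layout("toy9")

nb_chan = mv.channel_neighborhood(ds, layout, count=4,
                                  chantype="combined_from_planar")
nb_time = mv.interval_neighborhood(ds, "time", radius=1)
nb = mv.cross_neighborhood(ds, [nb_chan, nb_time])
print(f"channel neighborhood: {nb_chan.n_centers} centers; "
      f"time neighborhood: {nb_time.n_centers} centers; "
      f"crossed: {nb.n_centers} centers")

parts = mv.make_partitions(ds, "nfold")
acc_map = mv.searchlight(ds, nb, mv.crossvalidation_measure,
                         opt={"partitions": parts})
print(f"accuracy map: {acc_map.samples.shape[0]} sample x "
      f"{acc_map.n_features} features "
      f"(dims {acc_map.a.fdim.labels})")
print(f"accuracy range: [{acc_map.samples.min():.2f}, "
      f"{acc_map.samples.max():.2f}]  (chance = 1/3)")

mv.export_table(acc_map, "/tmp/chan_time_accuracy.tsv")
print("wrote /tmp/chan_time_accuracy.tsv "
      "(one row per channel/time cell with its accuracy)")
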