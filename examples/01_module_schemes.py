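"""Build the 7- and 17-network module schemes and inspect the edge-family
taxonomy that organises all downstream statistics."""

from collections import Counter

import strokeconn as sc
from strokeconn.parcellation import edge_families

seven = sc.build_scheme("seven")
seventeen = sc.build_scheme("seventeen")

print(f"seven-network scheme: {seven.total_count} modules "
      f"-> {seven.n_edges} unordered edges")
print(f"seventeen-network scheme: {seventeen.total_count} modules "
      f"-> {seventeen.n_edges} edges "
      f"({seventeen.count(sc.Structure.CEREBELLUM)} cerebellar modules; "
      "cerebellar VN A is excluded)")

print("\nfirst modules in matrix order:")
for m in seven.modules[:4]:
    print(f"  {m.index}: {m.name}")

counts = Counter(f.value for f in edge_families(seven))
print("\nedge-family sizes (seven scheme):")
for fam, n in sorted(counts.items()):
    print(f"  {fam:>24}: {n}")
print("The ten families partition all 378 edges: cerebral (91), "
      "cerebellar (91), cerebro-cerebellar (196).")
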