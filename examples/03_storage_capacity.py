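"""How many bits can a synapse store?  Weight vs total capacity.

The classic Willshaw bound limits weight plasticity to ln 2 ~ 0.69 bits per
synapse.  Normalising the stored information by the consolidated synapses
only — the budget structural plasticity actually spends — the capacity per
synapse grows without bound for sparse assemblies as the network gets
larger.
"""

from plastinet import CapacityQuery, pattern_capacity, weight_capacity, \
    total_capacity, pattern_capacity_finite

print("Asymptotic analysis, full connectivity, noiseless queries (eps=0.01):")
print(f"{'n':>9} {'M_eps':>12} {'C_weight':>10} {'C_total':>9}")
for n in (10 ** 3, 10 ** 4, 10 ** 5, 10 ** 6):
    q = CapacityQuery(m=n, n=n, k=10, l=10, eps=0.01, P=1.0)
    print(f"{n:>9} {pattern_capacity(q):>12} {weight_capacity(q):>10.3f} "
          f"{total_capacity(q):>9.3f}")
print("(C in bits/synapse; C_weight stays below ln 2 = 0.693, C_total "
      "diverges with n: selecting synapse locations stores information)")

print("\nFinite-network Gaussian analysis (n=1000, k=30, output noise 0.2):")
for ce in (0.3, 0.5, 0.8):
    r = pattern_capacity_finite(
        CapacityQuery(m=1000, n=1000, k=30, l=30, eps=0.2, P=ce))
    print(f"  effectual connectivity {ce:.1f}: M_eps = {r.M_eps:5d} memories, "
          f"optimal threshold {r.theta_opt}")
print("(raising effectual connectivity -- what structural plasticity does -- "
      "multiplies the number of storable memories)")
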