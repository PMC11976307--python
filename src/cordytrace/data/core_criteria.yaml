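# Core production-region criteria for the Chinese caterpillar fungus
# (Ophiocordyceps sinensis), dual-barcode edition.
#
# The explicit core marker sets are the published hallmark haplotypes of the
# high-quality ("core") production belt on the central Tibetan Plateau.  When
# explicit sets are given they take precedence; the derivation fields
# (core clades + reference regions) exist for applying the same procedure to
# new datasets where the hallmark sets are unknown.
name: published-core-criteria

# Reference regions recognised as core production by the trade.  Prefecture
# level entries mean every county of that prefecture; county lists refine a
# prefecture to specific counties.
core_reference_regions:
  - {province: Xizang, prefecture: Nagqu}
  - {province: Xizang, prefecture: Qamdo}
  - {province: Qinghai, prefecture: Yushu}
  - {province: Qinghai, prefecture: Guoluo}
  - {province: Gansu, prefecture: Gannan, counties: [Maqu, Xiahe]}
  - {province: Xizang, prefecture: Nyingch, counties: [Bomi, Zayü]}
  - {province: Xizang, prefecture: Lhasa, counties: [Damxung]}
  - {province: Sichuan, prefecture: Garzê, counties: [Sêrxü]}

# Hallmark (core) marker haplotypes.  These override derivation.
explicit_core_its: [F01, F04, F07, F19, F23]
explicit_core_coi: [H02, H03, H04, H15, H16, H17, H23, H24, H28, H32, H33,
                    H36, H51, H59, H67, H68, H69, H70, H71, H72, H74, H75,
                    H76, H78]

# Derivation mode (used only when the explicit sets above are absent):
# a marker haplotype is core when its clade is listed in core_*_clades
# and/or it occurs in a core reference region, controlled by region_rule
# ("and" | "or" | "ignore").
core_its_clades: []
core_coi_clades: []
clade_map: {}
region_rule: and
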