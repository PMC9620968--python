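# Glycosidic-linkage library for GPI glycolipid variants.
#
# This file is data, not code: edit it to match the atom naming of your
# force field / topology. Each quadruple is four selection expressions,
# each of which must resolve to exactly one atom.
#
# Conventions (parent = non-reducing "1" end, child = acceptor):
#   phi   = (parent C2, parent C1, child Ox, child Cx)
#   psi   = (parent C1, child Ox, child Cx, child Cy)   Cy = C(x+1), C5 for x=6
#   omega = (child O6, child C6, child C5, child O5)    1->6 linkages only
#
# GlcN-Ino is a 1->6 attachment onto a carbocycle (myo-inositol has no
# ring oxygen O5), so it carries no omega torsion.
#
# Residue names use the 5-character truncations found in GRO files
# (GalNA = GalNAc, GlcNA = GlcNAc). The anomeric class of the side-branch
# attachments (GalNAc-Man1, Glc-GalNAc, GlcNAc-Man1) is encoded from
# common usage for these structures; edit if your variant differs.

core: &man3_man2
  name: Man3-a12-Man2
  class: "1->2"
  phi:   ["resname Man3 and name C2", "resname Man3 and name C1",
          "resname Man2 and name O2", "resname Man2 and name C2"]
  psi:   ["resname Man3 and name C1", "resname Man2 and name O2",
          "resname Man2 and name C2", "resname Man2 and name C3"]

core2: &man2_man1
  name: Man2-a16-Man1
  class: "1->6"
  phi:   ["resname Man2 and name C2", "resname Man2 and name C1",
          "resname Man1 and name O6", "resname Man1 and name C6"]
  psi:   ["resname Man2 and name C1", "resname Man1 and name O6",
          "resname Man1 and name C6", "resname Man1 and name C5"]
  omega: ["resname Man1 and name O6", "resname Man1 and name C6",
          "resname Man1 and name C5", "resname Man1 and name O5"]

core3: &man1_glcn
  name: Man1-a14-GlcN
  class: "1->4"
  phi:   ["resname Man1 and name C2", "resname Man1 and name C1",
          "resname GlcN and name O4", "resname GlcN and name C4"]
  psi:   ["resname Man1 and name C1", "resname GlcN and name O4",
          "resname GlcN and name C4", "resname GlcN and name C5"]

core4: &glcn_ino
  name: GlcN-a16-Ino
  class: "1->6"
  phi:   ["resname GlcN and name C2", "resname GlcN and name C1",
          "resname Ino and name O6", "resname Ino and name C6"]
  psi:   ["resname GlcN and name C1", "resname Ino and name O6",
          "resname Ino and name C6", "resname Ino and name C5"]

branch_galnac: &galnac_man1
  name: GalNAc-b14-Man1
  class: "1->4"
  phi:   ["resname GalNA and name C2", "resname GalNA and name C1",
          "resname Man1 and name O4", "resname Man1 and name C4"]
  psi:   ["resname GalNA and name C1", "resname Man1 and name O4",
          "resname Man1 and name C4", "resname Man1 and name C5"]

branch_glc: &glc_galnac
  name: Glc-a14-GalNAc
  class: "1->4"
  phi:   ["resname Glc and name C2", "resname Glc and name C1",
          "resname GalNA and name O4", "resname GalNA and name C4"]
  psi:   ["resname Glc and name C1", "resname GalNA and name O4",
          "resname GalNA and name C4", "resname GalNA and name C5"]

branch_glcnac: &glcnac_man1
  name: GlcNAc-b14-Man1
  class: "1->4"
  phi:   ["resname GlcNA and name C2", "resname GlcNA and name C1",
          "resname Man1 and name O4", "resname Man1 and name C4"]
  psi:   ["resname GlcNA and name C1", "resname Man1 and name O4",
          "resname Man1 and name C4", "resname Man1 and name C5"]

branch_gal: &gal_glcnac
  name: Gal-b16-GlcNAc
  class: "1->6"
  phi:   ["resname Gal and name C2", "resname Gal and name C1",
          "resname GlcNA and name O6", "resname GlcNA and name C6"]
  psi:   ["resname Gal and name C1", "resname GlcNA and name O6",
          "resname GlcNA and name C6", "resname GlcNA and name C5"]
  omega: ["resname GlcNA and name O6", "resname GlcNA and name C6",
          "resname GlcNA and name C5", "resname GlcNA and name O5"]

variants:
  # conserved tetrasaccharide core only
  gpi0: [*man3_man2, *man2_man1, *man1_glcn, *glcn_ino]
  # + GalNAc side branch on Man1 (T. gondii)
  gpi1: [*man3_man2, *man2_man1, *man1_glcn, *glcn_ino, *galnac_man1]
  # + terminal Glc on GalNAc (T. gondii LMW)
  gpi2: [*man3_man2, *man2_man1, *man1_glcn, *glcn_ino, *galnac_man1,
         *glc_galnac]
  # GlcNAc on Man1 + terminal Gal (T. congolense)
  gpi3: [*man3_man2, *man2_man1, *man1_glcn, *glcn_ino, *glcnac_man1,
         *gal_glcnac]
  # human core (mPEtN decoration is a phosphodiester, not a glycosidic
  # linkage, and is not listed here)
  gpi4: [*man3_man2, *man2_man1, *man1_glcn, *glcn_ino]
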