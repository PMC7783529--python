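# Anatomy table for the young-adult C. elegans hermaphrodite.
# Compiled from WormAtlas (wormatlas.org) and the WormBase anatomy
# ontology (WBbt, via the WormBase ontology browser / Ontobee); syncytial
# nuclei counts cross-checked against Shemer & Podbilewicz (2000), Table 1.
# Schema: cell,tissue,somatic,nuclei,ploidy_c
#   nuclei   = nuclei in the (possibly syncytial) cell; 0 only for the
#              extracellular cuticle
#   ploidy_c = DNA content per nucleus as a C-value (2 = diploid).
# Conventions adopted here:
#   - Intestinal nuclei endoreduplicate to 32C by the young-adult stage;
#     cells are recorded mononucleate with ploidy_c=32, i.e. 16 diploid
#     genome equivalents per cell.  Binucleate variants can be expressed
#     by editing nuclei/ploidy_c per cell.
#   - The germline (rachis plus germ-cell and sperm nuclei) is one
#     non-somatic pseudo-record; its nuclei count (~2000 for both gonad
#     arms, including ~300 sperm) is a literature point estimate within a
#     range (sperm: Singson 2001; germ cells: Diag, Schilling et al. 2018).
#   - The adult lateral seam is recorded as one fused syncytium per side.
#   - Spermatheca and uterus are recorded as per-organ aggregates
#     (annotated; not syncytia) because their many small cells are not
#     individually resolved in mesh models.
#   - The neuron list is a representative subset of the 302-neuron
#     complement; users may substitute a complete per-neuron table.
cell,tissue,somatic,nuclei,ploidy_c
hyp1,hypodermis,true,3,2
hyp2,hypodermis,true,2,2
hyp3,hypodermis,true,2,2
hyp4,hypodermis,true,3,2
hyp5,hypodermis,true,2,2
hyp6,hypodermis,true,3,2
hyp7,hypodermis,true,139,2
hyp8,hypodermis,true,1,2
hyp9,hypodermis,true,1,2
hyp10,hypodermis,true,1,2
hyp11,hypodermis,true,1,2
seamL,hypodermis,true,16,2
seamR,hypodermis,true,16,2
cuticle,cuticle,true,0,2
pm1,pharynx,true,6,2
pm2,pharynx,true,3,2
pm3,pharynx,true,3,2
pm4,pharynx,true,3,2
pm5,pharynx,true,3,2
pm6,pharynx,true,3,2
pm7,pharynx,true,3,2
pm8,pharynx,true,1,2
mc1,pharynx,true,3,2
mc2,pharynx,true,2,2
mc3,pharynx,true,2,2
g1,pharynx,true,3,2
g2,pharynx,true,2,2
int1DL,intestine,true,1,32
int1DR,intestine,true,1,32
int1VL,intestine,true,1,32
int1VR,intestine,true,1,32
int2L,intestine,true,1,32
int2R,intestine,true,1,32
int3L,intestine,true,1,32
int3R,intestine,true,1,32
int4L,intestine,true,1,32
int4R,intestine,true,1,32
int5L,intestine,true,1,32
int5R,intestine,true,1,32
int6L,intestine,true,1,32
int6R,intestine,true,1,32
int7L,intestine,true,1,32
int7R,intestine,true,1,32
int8L,intestine,true,1,32
int8R,intestine,true,1,32
int9L,intestine,true,1,32
int9R,intestine,true,1,32
MDL01,body wall muscle,true,1,2
MDL02,body wall muscle,true,1,2
MDL03,body wall muscle,true,1,2
MDL04,body wall muscle,true,1,2
MDL05,body wall muscle,true,1,2
MDL06,body wall muscle,true,1,2
MDL07,body wall muscle,true,1,2
MDL08,body wall muscle,true,1,2
MDL09,body wall muscle,true,1,2
MDL10,body wall muscle,true,1,2
MDL11,body wall muscle,true,1,2
MDL12,body wall muscle,true,1,2
MDL13,body wall muscle,true,1,2
MDL14,body wall muscle,true,1,2
MDL15,body wall muscle,true,1,2
MDL16,body wall muscle,true,1,2
MDL17,body wall muscle,true,1,2
MDL18,body wall muscle,true,1,2
MDL19,body wall muscle,true,1,2
MDL20,body wall muscle,true,1,2
MDL21,body wall muscle,true,1,2
MDL22,body wall muscle,true,1,2
MDL23,body wall muscle,true,1,2
MDL24,body wall muscle,true,1,2
MDR01,body wall muscle,true,1,2
MDR02,body wall muscle,true,1,2
MDR03,body wall muscle,true,1,2
MDR04,body wall muscle,true,1,2
MDR05,body wall muscle,true,1,2
MDR06,body wall muscle,true,1,2
MDR07,body wall muscle,true,1,2
MDR08,body wall muscle,true,1,2
MDR09,body wall muscle,true,1,2
MDR10,body wall muscle,true,1,2
MDR11,body wall muscle,true,1,2
MDR12,body wall muscle,true,1,2
MDR13,body wall muscle,true,1,2
MDR14,body wall muscle,true,1,2
MDR15,body wall muscle,true,1,2
MDR16,body wall muscle,true,1,2
MDR17,body wall muscle,true,1,2
MDR18,body wall muscle,true,1,2
MDR19,body wall muscle,true,1,2
MDR20,body wall muscle,true,1,2
MDR21,body wall muscle,true,1,2
MDR22,body wall muscle,true,1,2
MDR23,body wall muscle,true,1,2
MDR24,body wall muscle,true,1,2
MVL01,body wall muscle,true,1,2
MVL02,body wall muscle,true,1,2
MVL03,body wall muscle,true,1,2
MVL04,body wall muscle,true,1,2
MVL05,body wall muscle,true,1,2
MVL06,body wall muscle,true,1,2
MVL07,body wall muscle,true,1,2
MVL08,body wall muscle,true,1,2
MVL09,body wall muscle,true,1,2
MVL10,body wall muscle,true,1,2
MVL11,body wall muscle,true,1,2
MVL12,body wall muscle,true,1,2
MVL13,body wall muscle,true,1,2
MVL14,body wall muscle,true,1,2
MVL15,body wall muscle,true,1,2
MVL16,body wall muscle,true,1,2
MVL17,body wall muscle,true,1,2
MVL18,body wall muscle,true,1,2
MVL19,body wall muscle,true,1,2
MVL20,body wall muscle,true,1,2
MVL21,body wall muscle,true,1,2
MVL22,body wall muscle,true,1,2
MVL23,body wall muscle,true,1,2
MVR01,body wall muscle,true,1,2
MVR02,body wall muscle,true,1,2
MVR03,body wall muscle,true,1,2
MVR04,body wall muscle,true,1,2
MVR05,body wall muscle,true,1,2
MVR06,body wall muscle,true,1,2
MVR07,body wall muscle,true,1,2
MVR08,body wall muscle,true,1,2
MVR09,body wall muscle,true,1,2
MVR10,body wall muscle,true,1,2
MVR11,body wall muscle,true,1,2
MVR12,body wall muscle,true,1,2
MVR13,body wall muscle,true,1,2
MVR14,body wall muscle,true,1,2
MVR15,body wall muscle,true,1,2
MVR16,body wall muscle,true,1,2
MVR17,body wall muscle,true,1,2
MVR18,body wall muscle,true,1,2
MVR19,body wall muscle,true,1,2
MVR20,body wall muscle,true,1,2
MVR21,body wall muscle,true,1,2
MVR22,body wall muscle,true,1,2
MVR23,body wall muscle,true,1,2
MVR24,body wall muscle,true,1,2
ADAL,neurons,true,1,2
ADAR,neurons,true,1,2
ADEL,neurons,true,1,2
ADER,neurons,true,1,2
ADFL,neurons,true,1,2
ADFR,neurons,true,1,2
ADLL,neurons,true,1,2
ADLR,neurons,true,1,2
AFDL,neurons,true,1,2
AFDR,neurons,true,1,2
AIYL,neurons,true,1,2
AIYR,neurons,true,1,2
ALA,neurons,true,1,2
ALML,neurons,true,1,2
ALMR,neurons,true,1,2
ASEL,neurons,true,1,2
ASER,neurons,true,1,2
AVAL,neurons,true,1,2
AVAR,neurons,true,1,2
AVBL,neurons,true,1,2
AVBR,neurons,true,1,2
AWAL,neurons,true,1,2
AWAR,neurons,true,1,2
AWBL,neurons,true,1,2
AWBR,neurons,true,1,2
AWCL,neurons,true,1,2
AWCR,neurons,true,1,2
BDUL,neurons,true,1,2
BDUR,neurons,true,1,2
CANL,neurons,true,1,2
CANR,neurons,true,1,2
DVA,neurons,true,1,2
DVB,neurons,true,1,2
DVC,neurons,true,1,2
HSNL,neurons,true,1,2
HSNR,neurons,true,1,2
PLML,neurons,true,1,2
PLMR,neurons,true,1,2
PVCL,neurons,true,1,2
PVCR,neurons,true,1,2
RID,neurons,true,1,2
RIS,neurons,true,1,2
dtc_ant,somatic gonad,true,1,2
dtc_post,somatic gonad,true,1,2
sheath1a,somatic gonad,true,1,2
sheath2a,somatic gonad,true,1,2
sheath3a,somatic gonad,true,1,2
sheath4a,somatic gonad,true,1,2
sheath5a,somatic gonad,true,1,2
sheath1p,somatic gonad,true,1,2
sheath2p,somatic gonad,true,1,2
sheath3p,somatic gonad,true,1,2
sheath4p,somatic gonad,true,1,2
sheath5p,somatic gonad,true,1,2
spermatheca_ant,somatic gonad,true,24,2
spermatheca_post,somatic gonad,true,24,2
uterus,somatic gonad,true,46,2
germline,germline,false,2000,2
exc_cell,other,true,1,2
exc_duct,other,true,1,2
exc_pore,other,true,1,2
exc_gland,other,true,2,2
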