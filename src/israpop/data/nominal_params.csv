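name,value,units,status,soft_lo,soft_hi,hard_lo,hard_hi
ven_k_uptake,0.14546313762494611,1/h,free,0.05,0.2,0.005000000000000001,2.0
ven_k_decay_ext,0.027183001449300227,1/h,free,0.015,0.06,0.0015,0.6
ven_k_decay_int,0.027755883130429305,1/h,free,0.01,0.04,0.001,0.4
ted_k_uptake,0.02343577907889149,1/h,free,0.015,0.06,0.0015,0.6
ted_k_decay_ext,0.0107388669657274,1/h,free,0.005,0.02,0.0005,0.2
ted_k_decay_int,0.00970876923937289,1/h,free,0.005,0.02,0.0005,0.2
myc_prod_basal,23.75222950421653,nM/h,free,10.0,40.0,1.0,400.0
myc_deg,0.18809793063321348,1/h,free,0.1,0.4,0.010000000000000002,4.0
chop_prod_basal,6.031317575848878,nM/h,free,2.5,10.0,0.25,100.0
chop_deg,0.2294987351529863,1/h,free,0.125,0.5,0.0125,5.0
myc_ven_amp,0.3013962122770386,-,free,0.0,1.0,0.0,1.0
myc_ven_K,176.29459111417833,nM,free,100.0,400.0,10.0,4000.0
myc_ven_n,2.3842832394167415,-,free,1.0,4.0,0.5,10.0
myc_ted_amp,-0.40911307287257326,-,free,-0.9,0.0,-0.99,0.0
myc_ted_K,1123.418179390831,nM,free,600.0,2400.0,60.0,24000.0
myc_ted_n,3.3866629020406336,-,free,1.0,4.0,0.5,10.0
chop_ven_amp,1.3655984367649123,-,free,0.0,4.0,0.0,40.0
chop_ven_K,291.4751766435555,nM,free,100.0,400.0,10.0,4000.0
chop_ven_n,1.1893145277786863,-,free,1.0,4.0,0.5,10.0
chop_ted_amp,2.8449832007544282,-,free,0.5,8.0,0.0,80.0
chop_ted_K,1675.1436291754426,nM,free,750.0,3000.0,75.0,30000.0
chop_ted_n,1.0412843483735588,-,free,1.0,4.0,0.5,10.0
chop_syn_amp,10.22468418466321,-,free,1.0,20.0,0.1,200.0
myc_ven_tau,3.4244131913530604,h,free,0.0,24.0,0.0,48.0
myc_ted_tau,9.89296339464252,h,free,0.0,24.0,0.0,48.0
chop_ven_tau,13.732563639012989,h,free,0.0,24.0,0.0,48.0
chop_ted_tau,12.066395575497364,h,free,0.0,24.0,0.0,48.0
bcl2_0,203.95804324721422,nM,free,60.0,240.0,6.0,2400.0
mcl1_0,186.85937057574156,nM,free,75.0,300.0,7.5,3000.0
bim_0,109.15443817696317,nM,free,40.0,160.0,4.0,1600.0
bax_0,96.65765455313382,nM,free,50.0,200.0,5.0,2000.0
bak_0,67.67382007122487,nM,free,50.0,200.0,5.0,2000.0
casp3_0,100.0,nM,fixed,50.0,200.0,5.0,2000.0
bcl2_deg,0.1333865860128723,1/h,free,0.04,0.16,0.004,1.6
mcl1_deg,0.5096811886525382,1/h,free,0.175,0.7,0.017499999999999998,7.0
bim_deg,0.20044494916824585,1/h,free,0.06,0.24,0.006,2.4
bax_deg,0.07007410075172106,1/h,free,0.025,0.1,0.0025000000000000005,1.0
bak_deg,0.07224277243701177,1/h,free,0.025,0.1,0.0025000000000000005,1.0
baxA_deg,0.17955209675501518,1/h,free,0.05,0.2,0.005000000000000001,2.0
bakA_deg,0.12255263308716793,1/h,free,0.05,0.2,0.005000000000000001,2.0
cx_deg,0.13958836873389716,1/h,free,0.05,0.2,0.005000000000000001,2.0
cleaved_deg,0.11927917474942833,1/h,free,0.05,0.2,0.005000000000000001,2.0
reg_myc_bcl2_up_amp,2.6639659117484635,-,free,0.2,4.0,0.0,40.0
reg_myc_bcl2_up_K,103.42099637354238,nM,free,40.0,160.0,4.0,1600.0
reg_myc_bcl2_up_n,2.1422963785797906,-,free,1.0,4.0,0.5,10.0
reg_myc_bcl2_down_amp,0.6995429008859658,-,free,0.1,0.95,0.0,1.0
reg_myc_bcl2_down_K,616.6737469455167,nM,free,200.0,800.0,20.0,8000.0
reg_myc_bcl2_down_n,4.862141365333627,-,free,2.0,8.0,0.5,10.0
reg_myc_mcl1_up_amp,3.659664807880504,-,free,0.2,4.0,0.0,40.0
reg_myc_mcl1_up_K,89.41060741163685,nM,free,50.0,200.0,5.0,2000.0
reg_myc_mcl1_up_n,2.1151248041186377,-,free,1.0,4.0,0.5,10.0
reg_myc_bim_up_amp,0.7736117106504833,-,free,0.2,4.0,0.0,40.0
reg_myc_bim_up_K,516.3687431041027,nM,free,150.0,600.0,15.0,6000.0
reg_myc_bim_up_n,3.196778930242339,-,free,2.0,8.0,0.5,10.0
reg_myc_bax_up_amp,2.5622271202297036,-,free,0.2,4.0,0.0,40.0
reg_myc_bax_up_K,389.2673395338488,nM,free,175.0,700.0,17.5,7000.0
reg_myc_bax_up_n,4.834847811077017,-,free,2.0,8.0,0.5,10.0
reg_myc_bak_up_amp,2.222882834905256,-,free,0.2,4.0,0.0,40.0
reg_myc_bak_up_K,438.4473553154631,nM,free,160.0,640.0,16.0,6400.0
reg_myc_bak_up_n,2.1793787219100325,-,free,2.0,8.0,0.5,10.0
reg_chop_bim_up_amp,1.2547537311855124,-,free,0.2,4.0,0.0,40.0
reg_chop_bim_up_K,93.83696384152488,nM,free,50.0,200.0,5.0,2000.0
reg_chop_bim_up_n,3.5952047033857317,-,free,1.0,4.0,0.5,10.0
reg_chop_bak_up_amp,3.301708950364341,-,free,0.2,6.0,0.0,60.0
reg_chop_bak_up_K,159.9802006088144,nM,free,50.0,200.0,5.0,2000.0
reg_chop_bak_up_n,1.7815946825716638,-,free,1.0,4.0,0.5,10.0
reg_chop_bax_up_amp,0.4930938038229616,-,free,0.0,1.0,0.0,1.0
reg_chop_bax_up_K,246.2153218716337,nM,free,75.0,300.0,7.5,3000.0
reg_chop_bax_up_n,2.568703020025142,-,free,1.0,4.0,0.5,10.0
reg_chop_mcl1_down_amp,0.9763627476293077,-,free,0.1,0.98,0.0,1.0
reg_chop_mcl1_down_K,68.06928380660453,nM,free,30.0,120.0,3.0,1200.0
reg_chop_mcl1_down_n,1.4166585816571795,-,free,1.0,4.0,0.5,10.0
reg_chop_bcl2_down_amp,0.2988196533956534,-,free,0.0,0.5,0.0,1.0
reg_chop_bcl2_down_K,138.58040784368927,nM,free,75.0,300.0,7.5,3000.0
reg_chop_bcl2_down_n,2.263862186379889,-,free,1.0,4.0,0.5,10.0
kon_bcl2_bim,1.0,1/(nM h),fixed,0.5,2.0,0.05,20.0
koff_bcl2_bim,10.0,1/h,fixed,5.0,20.0,0.5,200.0
kon_bcl2_baxA,1.0,1/(nM h),fixed,0.5,2.0,0.05,20.0
koff_bcl2_baxA,15.0,1/h,fixed,7.5,30.0,0.75,300.0
kon_bcl2_bakA,1.0,1/(nM h),fixed,0.5,2.0,0.05,20.0
koff_bcl2_bakA,15.0,1/h,fixed,7.5,30.0,0.75,300.0
kon_mcl1_bim,1.0,1/(nM h),fixed,0.5,2.0,0.05,20.0
koff_mcl1_bim,10.0,1/h,fixed,5.0,20.0,0.5,200.0
kon_mcl1_baxA,1.0,1/(nM h),fixed,0.5,2.0,0.05,20.0
koff_mcl1_baxA,25.0,1/h,fixed,12.5,50.0,1.25,500.0
kon_mcl1_bakA,1.0,1/(nM h),fixed,0.5,2.0,0.05,20.0
koff_mcl1_bakA,20.0,1/h,fixed,10.0,40.0,1.0,400.0
kon_bim_bax,0.5,1/(nM h),fixed,0.25,1.0,0.025,10.0
koff_bim_bax,50.0,1/h,fixed,25.0,100.0,2.5,1000.0
kon_bim_bak,0.5,1/(nM h),fixed,0.25,1.0,0.025,10.0
koff_bim_bak,50.0,1/h,fixed,25.0,100.0,2.5,1000.0
kon_bcl2_ven,2.0,1/(nM h),fixed,1.0,4.0,0.1,40.0
koff_bcl2_ven,2.0,1/h,fixed,1.0,4.0,0.1,40.0
k_act_bax,0.7232981304627416,1/h,free,0.25,1.0,0.025,10.0
k_act_bak,0.7303946704959435,1/h,free,0.25,1.0,0.025,10.0
k_casp_act,0.9084094692176855,1/h,free,0.35,1.4,0.034999999999999996,14.0
K_momp,98.85543690783076,nM,free,25.0,100.0,2.5,1000.0
momp_n,3.0623451371681107,-,free,2.0,8.0,2.0,10.0
k_casp_deact,0.06829130246204787,1/h,free,0.04,0.16,0.004,1.6
k_cleave_bcl2,0.018502210197803376,1/(nM h),free,0.005,0.02,0.0005,0.2
k_cleave_mcl1,0.009013756727641885,1/(nM h),free,0.005,0.02,0.0005,0.2
g0,0.03216042872336843,1/h,free,0.016,0.064,0.0016,0.64
growth_bcl2_K,5.190312004998757,nM,free,1.5,6.0,0.15000000000000002,60.0
growth_bcl2_n,1.1154653532835621,-,free,0.5,2.0,0.5,10.0
growth_ted_K,966.2429198019692,nM,free,300.0,1200.0,30.0,12000.0
growth_ted_n,2.504119998789534,-,free,0.5,4.0,0.5,10.0
growth_myc_amp,0.1629011732115729,-,free,0.0,1.0,0.0,5.0
growth_myc_K,212.58309922929456,nM,free,75.0,300.0,7.5,3000.0
growth_myc_n,1.7475417213636342,-,free,1.0,4.0,0.5,10.0
d0,0.0016367204986279848,1/h,free,0.0005,0.002,5e-05,0.02
d_max,0.06557112436088164,1/h,free,0.02,0.08,0.002,0.8
death_frac_K,0.019373134690696986,-,free,0.01,0.04,0.001,0.4
death_frac_n,3.0285567170853263,-,free,1.0,6.0,0.5,10.0
n_live_0,1.0,-,fixed,0.5,2.0,0.05,20.0
n_dead_0,0.02,-,fixed,0.01,0.04,0.001,0.4
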