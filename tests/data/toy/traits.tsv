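line	environment	trait	value
RIL001	E1	SWP	14.631448528092207
RIL002	E1	SWP	12.492980814199298
RIL003	E1	SWP	17.480615443657232
RIL004	E1	SWP	15.40076828260576
RIL005	E1	SWP	17.421818492762135
RIL006	E1	SWP	18.274149949868235
RIL007	E1	SWP	18.34187647509216
RIL008	E1	SWP	11.740270582607051
RIL001	E2	SWP	9.859212276338308
RIL002	E2	SWP	18.170168067533236
RIL003	E2	SWP	18.673766740602424
RIL004	E2	SWP	14.78642767139015
RIL005	E2	SWP	15.398625959682503
RIL006	E2	SWP	22.310233669225937
RIL007	E2	SWP	18.695704800693047
RIL008	E2	SWP	11.11463272700907
RIL001	E1	TGW	3.2961223759739258
RIL002	E1	TGW	3.272975510081682
RIL003	E1	TGW	3.0910678377571323
RIL004	E1	TGW	2.771328113173112
RIL005	E1	TGW	3.203225312133433
RIL006	E1	TGW	2.9581447969315207
RIL007	E1	TGW	3.572591430737682
RIL008	E1	TGW	2.848972702946562
RIL001	E2	TGW	3.5687018427739954
RIL002	E2	TGW	3.434345407812488
RIL003	E2	TGW	3.4089859441260204
RIL004	E2	TGW	3.505533215579193
RIL005	E2	TGW	3.1907183083141932
RIL006	E2	TGW	3.169731469366258
RIL007	E2	TGW	3.3280086660776265
RIL008	E2	TGW	3.4902339062377283
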