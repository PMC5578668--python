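Haplotype	15494	15495	15496	15534	15538	15542	15601	15602	15603	15635	15649	15666	15667	15703	15709	15720	15771	15777	15806	15807	15809	15826	15827	15838	15869	15870	15871	15956	15974	16009	16033	16040	16057	16068	16071	16079	16371	16442	16543	16546	16559	16635
Ref	T	T	A	C	A	C	T	C	T	C	A	G	A	T	C	G	C	A	C	C	A	A	A	C	C	C	C	A	C	T	T	A	A	T	T	A	T	C	T	T	C	A
M1		C										A				A						G											G				C					
M2		C			G			T							T	A	T					G				T			T								C	T				
M3		C										A				A																	G				C					
M4		C				T		T		T		A		C		A										T					C						C					
M5		C						T					G	C		A	T	G			G							G				G					C		A			G
M6		C						T								A						G				T		G	T								C					
M7		C				T		T		T		A				A										T											C					
M8		C					C	T								A	T		T				G	T	T			G		C					C		C		A	C	T	G
M9		C			G			T								A	T					G							T								C					
M10	C	C	G	T				T	C		G					A	T			T						T	T	G	T					C		G	C					
#insertion	M9	16371	C
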