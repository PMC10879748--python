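{"signature":[1,2,2,2],"reduced":[["m",0],["m",1],["m",2],["m",3],["m",4],["m",5],["m",6],["m",7],["m",8],["u1",9],["u2",9],["m",10],["m",11],["m",12]],"provenance":"numeric-interpolation","max_degree":2,"polys":[[[1,1,[0]],[-3,1,[1,7]],[3,1,[1,11]],[-3,1,[2,8]]],[[1,1,[1]],[-1,2,[8]],[-3,2,[1,10]],[-1,1,[6,9]],[-1,2,[6,10]],[1,2,[8,9]],[1,1,[8,10]]],[[1,1,[2]],[1,1,[7]],[-1,1,[11]],[-2,1,[2,9]],[-1,1,[2,10]]],[[1,1,[3]],[-3,2,[3,10]],[-3,1,[4,6]],[3,2,[4,8]]],[[1,1,[4]],[1,1,[12]],[-1,1,[13]],[-1,1,[4,9]],[-2,1,[4,10]]],[[1,1,[5]],[3,1,[4,7]],[-3,1,[4,11]],[-2,1,[5,9]],[-1,1,[5,10]]],[[1,1,[6]],[-1,1,[8]],[-1,1,[6,9]],[-1,2,[6,10]],[1,2,[8,9]],[1,1,[8,10]]],[[1,1,[0,4]],[-1,1,[3,7]],[1,1,[3,11]],[-1,1,[5,8]]],[[1,1,[0,9]],[-2,1,[1,7]],[2,1,[1,11]],[-1,1,[2,6]]],[[1,1,[0,10]],[-2,1,[1,7]],[2,1,[1,11]],[2,1,[2,6]],[-3,1,[2,8]]],[[1,1,[0,12]],[-1,1,[0,13]],[-1,1,[3,7]],[1,1,[3,11]],[1,1,[5,6]],[-1,1,[5,8]]],[[1,1,[1,2]],[-1,1,[1,7]],[1,1,[1,11]],[-1,1,[2,8]]],[[1,1,[1,4]],[-1,2,[3,10]],[-1,1,[4,6]],[1,2,[4,8]]],[[1,1,[1,5]],[-1,1,[3,7]],[1,1,[3,11]],[-1,1,[5,8]]],[[1,1,[1,9]],[-1,1,[1,10]],[-1,1,[6,9]],[-1,2,[6,10]],[1,2,[8,9]],[1,1,[8,10]]],[[1,1,[1,12]],[-1,1,[1,13]],[-1,2,[3,10]],[1,2,[4,8]]],[[1,1,[2,3]],[-1,1,[3,7]],[1,1,[3,11]],[-1,1,[5,8]]],[[1,1,[2,4]],[1,1,[4,7]],[-1,1,[4,11]],[-2,3,[5,9]],[-1,3,[5,10]]],[[1,1,[2,12]],[-1,1,[2,13]],[-1,1,[4,7]],[1,1,[4,11]],[1,3,[5,9]],[-1,3,[5,10]]],[[1,1,[3,9]],[-1,1,[3,10]],[-3,1,[4,6]],[3,1,[4,8]]],[[1,1,[3]],[-3,1,[1,12]],[3,1,[1,13]],[-3,1,[4,6]]],[[1,1,[1]],[-1,2,[6]],[-3,2,[1,9]],[1,1,[6,9]],[1,2,[6,10]],[-1,2,[8,9]],[-1,1,[8,10]]],[[1,1,[0]],[-3,2,[0,9]],[3,2,[2,6]],[-3,1,[2,8]]],[[1,1,[5]],[3,1,[2,12]],[-3,1,[2,13]],[-1,1,[5,9]],[-2,1,[5,10]]],[[1,1,[0,12]],[-1,1,[0,13]],[-1,1,[2,3]],[1,1,[5,6]]],[[2,1,[1,12]],[-2,1,[1,13]],[-1,1,[3,10]],[1,1,[4,8]]],[[2,1,[1,12]],[-2,1,[1,13]],[-1,1,[3,9]],[3,1,[4,6]],[-2,1,[4,8]]],[[1,1,[1,4]],[-1,1,[1,12]],[1,1,[1,13]],[-1,1,[4,6]]],[[1,2,[0,9]],[-1,1,[1,2]],[-1,2,[2,6]],[1,1,[2,8]]],[[1,1,[0,12]],[-1,1,[0,13]],[-1,1,[1,5]],[1,1,[5,6]]],[[1,2,[0,9]],[-1,1,[1,7]],[1,1,[1,11]],[-1,2,[2,6]]],[[1,1,[0,4]],[-1,1,[0,12]],[1,1,[0,13]],[-1,1,[5,6]]],[[1,1,[2,4]],[1,1,[2,12]],[-1,1,[2,13]],[-1,3,[5,9]],[-2,3,[5,10]]],[[1,1,[0,9]],[-1,1,[0,10]],[-3,1,[2,6]],[3,1,[2,8]]]],"checksum":"e90e5ae63060091e23066329110de90bc54f12ed97a4e531cee15d0121496453"}
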